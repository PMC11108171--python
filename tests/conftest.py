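import numpy as np
import pytest

from stromascope.imgio import LabelMask
from stromascope.segnet import STROMA_CLASSES, TUMOR_CLASSES
from stromascope.synthdata import SlideRecipe, generate_slide
from stromascope.tissue import tissue_mask


@pytest.fixture(scope="session")
def slide_pair():
    """One generated slide pair + tissue mask, shared across modules."""
    he, ihc, truth = generate_slide(SlideRecipe(seed=7, target_stroma_fraction=0.7))
    tis = tissue_mask(he)
    return he, ihc, truth, tis


def three_class_labels(truth) -> LabelMask:
    lab = np.zeros(truth.epithelium.data.shape, np.uint8)
    lab[truth.epithelium.data.astype(bool)] = 1
    lab[truth.tumor_epithelium.data.astype(bool)] = 2
    return LabelMask(lab, truth.epithelium.spacing_um, dict(TUMOR_CLASSES))


def stroma_labels(truth) -> LabelMask:
    return LabelMask(
        truth.stroma.data.astype(np.uint8),
        truth.stroma.spacing_um,
        dict(STROMA_CLASSES),
    )
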