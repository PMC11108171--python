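import numpy as np
import pytest
from shapely.geometry import Polygon
from skimage.measure import find_contours

from stromascope.imgio import (
    Annotation,
    AnnotationSet,
    ClinicalRecord,
    LabelMask,
    SlideImage,
    binary_mask,
    polygons_to_mask,
    rasterize_polygons,
    read_annotations,
    read_clinical,
    read_mask,
    read_region,
    read_slide,
    write_annotations,
    write_clinical,
    write_mask,
    write_slide,
)


def _point_in_polygon(x, y, verts):
    """Brute-force ray casting with on-edge counted as inside."""
    n = len(verts)
    inside = False
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # on-edge check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) < 1e-12 and min(x1, x2) - 1e-12 <= x <= max(x1, x2) + 1e-12 \
                and min(y1, y2) - 1e-12 <= y <= max(y1, y2) + 1e-12:
            return True
        if (y1 > y) != (y2 > y):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xint:
                inside = not inside
    return inside


class TestSlideImage:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SlideImage([np.zeros((4, 4, 3), np.uint8)], spacing_um=-1)
        with pytest.raises(ValueError):
            SlideImage(
                [np.zeros((8, 8, 3), np.uint8), np.zeros((4, 4, 3), np.uint8)],
                spacing_um=1.0,
                downsamples=[1, 0.5],
            )

    def test_png_roundtrip(self, tmp_path):
        rng = np.random.default_rng(0)
        img = rng.integers(0, 256, size=(64, 48, 3), dtype=np.uint8)
        slide = SlideImage([img], spacing_um=1.0)
        p = write_slide(tmp_path / "s.png", slide)
        back = read_slide(p)
        assert back.spacing_um == 1.0
        assert np.array_equal(back.levels[0], img)

    def test_pyramid_tiff_roundtrip(self, tmp_path):
        rng = np.random.default_rng(1)
        lv0 = rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)
        lv1 = lv0[::4, ::4]
        slide = SlideImage([lv0, lv1], spacing_um=0.25, downsamples=[1, 4])
        p = write_slide(tmp_path / "s.tiff", slide)
        back = read_slide(p)
        assert back.n_levels == 2
        assert back.dimensions(1) == (
            back.dimensions(0)[0] // 4,
            back.dimensions(0)[1] // 4,
        )
        for a, b in zip(back.levels, slide.levels):
            assert np.array_equal(a, b)

    def test_missing_spacing(self, tmp_path):
        import imageio.v3 as iio

        iio.imwrite(tmp_path / "x.png", np.zeros((4, 4, 3), np.uint8))
        with pytest.raises(ValueError, match="spacing"):
            read_slide(tmp_path / "x.png")
        slide = read_slide(tmp_path / "x.png", spacing_um=2.0)
        assert slide.spacing_um == 2.0

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_slide(tmp_path / "nope.png")


class TestReadRegion:
    @pytest.fixture()
    def tiny(self):
        img = np.arange(4 * 4 * 3, dtype=np.uint8).reshape(4, 4, 3)
        return SlideImage([img], spacing_um=1.0)

    def test_full_window(self, tiny):
        out = read_region(tiny, 0, (0, 0), (4, 4))
        assert np.array_equal(out, tiny.levels[0])

    def test_fully_outside_is_white(self, tiny):
        out = read_region(tiny, 0, (10, 10), (3, 3))
        assert (out == 255).all()

    def test_half_outside(self, tiny):
        # window columns 2..5: left half image content, right half white
        out = read_region(tiny, 0, (0, 2), (4, 4))
        expected = np.full((4, 4, 3), 255, np.uint8)
        expected[:, :2] = tiny.levels[0][:, 2:4]
        assert np.array_equal(out, expected)

    def test_negative_size(self, tiny):
        with pytest.raises(ValueError):
            read_region(tiny, 0, (0, 0), (-1, 4))

    def test_tiling_reproduces_level(self, tiny):
        rows = [
            np.concatenate(
                [read_region(tiny, 0, (r, c), (2, 2)) for c in (0, 2)], axis=1
            )
            for r in (0, 2)
        ]
        stitched = np.concatenate(rows, axis=0)
        assert np.array_equal(stitched, tiny.levels[0])


class TestRasterization:
    def _slide(self, n=20):
        return SlideImage([np.zeros((n, n, 3), np.uint8)], spacing_um=1.0)

    def test_square_covering_centers(self):
        ann = AnnotationSet(
            [Annotation("sq", "roi", Polygon([(-0.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-0.5, 9.5)]))]
        )
        mask = polygons_to_mask(ann, self._slide(), 0)
        assert int(mask.data.sum()) == 100

    def test_two_disjoint_squares(self):
        sq1 = Polygon([(-0.5, -0.5), (4.5, -0.5), (4.5, 4.5), (-0.5, 4.5)])
        sq2 = Polygon([(9.5, 9.5), (14.5, 9.5), (14.5, 14.5), (9.5, 14.5)])
        ann = AnnotationSet(
            [Annotation("a", "roi", sq1), Annotation("b", "roi", sq2)]
        )
        mask = polygons_to_mask(ann, self._slide(), 0)
        assert int(mask.data.sum()) == 25 + 25

    def test_triangle_matches_bruteforce_oracle(self):
        verts = [(2.3, 1.1), (17.2, 4.7), (6.4, 18.1)]
        ann = AnnotationSet([Annotation("t", "roi", Polygon(verts))])
        mask = polygons_to_mask(ann, self._slide(), 0).data.astype(bool)
        oracle = np.zeros((20, 20), bool)
        for r in range(20):
            for c in range(20):
                oracle[r, c] = _point_in_polygon(c, r, verts)
        assert np.array_equal(mask, oracle)

    def test_empty_selection_all_zero(self):
        ann = AnnotationSet([])
        mask = polygons_to_mask(ann, self._slide(), 0, role="tumor_bulk")
        assert mask.data.sum() == 0

    def test_level_scaling(self):
        img0 = np.zeros((20, 20, 3), np.uint8)
        slide = SlideImage([img0, img0[::2, ::2]], spacing_um=1.0, downsamples=[1, 2])
        sq = Polygon([(-0.5, -0.5), (9.5, -0.5), (9.5, 9.5), (-0.5, 9.5)])
        ann = AnnotationSet([Annotation("sq", "roi", sq)])
        mask = polygons_to_mask(ann, slide, level=1)
        assert int(mask.data.sum()) == 25  # centers 0,2,4,6,8 in both axes

    @pytest.mark.parametrize("rect", [(3, 9, 5, 15), (0, 20, 0, 20), (7, 8, 2, 3)])
    def test_marching_squares_roundtrip(self, rect):
        r0, r1, c0, c1 = rect
        mask = np.zeros((20, 20), bool)
        mask[r0:r1, c0:c1] = True
        padded = np.pad(mask, 1)  # closed contours even at the frame border
        contours = find_contours(padded.astype(float), 0.5)
        polys = [Polygon([(x - 1, y - 1) for y, x in cs]) for cs in contours]
        again = rasterize_polygons(polys, mask.shape)
        assert np.array_equal(again, mask)


class TestMaskIO:
    def test_roundtrip(self, tmp_path):
        data = np.array([[0, 1], [2, 0]], np.uint8)
        mask = LabelMask(data, 1.0, {0: "background", 1: "a", 2: "b"})
        p = write_mask(tmp_path / "m.png", mask)
        back = read_mask(p)
        assert np.array_equal(back.data, data)
        assert back.class_codes == mask.class_codes
        assert back.spacing_um == 1.0

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            LabelMask(np.array([[5]]), 1.0, {0: "background"})

    def test_binary_helper(self):
        m = binary_mask(np.eye(3, dtype=bool), 2.0)
        assert m.binary("foreground").sum() == 3


class TestAnnotations:
    def test_geojson_roundtrip(self, tmp_path):
        poly = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        ann = AnnotationSet([Annotation("bulk1", "tumor_bulk", poly)])
        p = write_annotations(tmp_path / "a.geojson", ann)
        back = read_annotations(p)
        assert len(back) == 1
        a = back.annotations[0]
        assert a.name == "bulk1" and a.role == "tumor_bulk"
        assert a.polygon.equals(poly)

    def test_degenerate_ring_rejected(self):
        with pytest.raises(ValueError):
            Annotation("bad", "roi", Polygon([(0, 0), (1, 1), (2, 2)]))


class TestClinical:
    def _write(self, tmp_path, rows):
        import pandas as pd

        df = pd.DataFrame(rows)
        p = tmp_path / "clin.csv"
        df.to_csv(p, index=False)
        return p

    def test_dead_uses_days_to_death(self, tmp_path):
        p = self._write(
            tmp_path,
            [dict(patient_id="P1", age=60, gender="female", vital_status="dead",
                  days_to_death=120, days_to_last_follow_up="")],
        )
        (rec,) = read_clinical(p)
        assert rec.survival_days == 120 and rec.event

    def test_alive_uses_follow_up(self, tmp_path):
        p = self._write(
            tmp_path,
            [dict(patient_id="P1", age=60, gender="male", vital_status="alive",
                  days_to_death="", days_to_last_follow_up=400)],
        )
        (rec,) = read_clinical(p)
        assert rec.survival_days == 400 and not rec.event

    def test_duplicate_id_rejected(self, tmp_path):
        rows = [
            dict(patient_id="P1", age=60, gender="male", vital_status="alive",
                 days_to_death="", days_to_last_follow_up=1),
        ] * 2
        with pytest.raises(ValueError, match="duplicate"):
            read_clinical(self._write(tmp_path, rows))

    def test_negative_days_rejected(self, tmp_path):
        p = self._write(
            tmp_path,
            [dict(patient_id="P1", age=60, gender="male", vital_status="dead",
                  days_to_death=-5, days_to_last_follow_up="")],
        )
        with pytest.raises(ValueError, match="negative"):
            read_clinical(p)

    def test_unknown_categorical_level(self, tmp_path):
        p = self._write(
            tmp_path,
            [dict(patient_id="P1", age=60, gender="male", vital_status="alive",
                  days_to_death="", days_to_last_follow_up=10)],
        )
        (rec,) = read_clinical(p)
        assert rec.origin == "unknown"

    def test_write_read_roundtrip(self, tmp_path):
        recs = [
            ClinicalRecord("P1", 61.5, "female", "dead", 100, slide_ids=["P1_S0"]),
            ClinicalRecord("P2", 70.0, "male", "alive", 250),
        ]
        p = write_clinical(tmp_path / "c.csv", recs)
        back = read_clinical(p)
        assert [r.patient_id for r in back] == ["P1", "P2"]
        assert back[0].survival_days == 100 and back[1].survival_days == 250
        assert back[0].slide_ids == ["P1_S0"]
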