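"""Survival analysis on TSR: slide selection, horizon classification with
cross-validated logistic regression, and Kaplan-Meier stratification at the
cohort-mean TSR.

Horizon labeling: a patient is positive when dead within the horizon,
negative when observed beyond it (dead or alive), and EXCLUDED when
censored before the horizon — censored-before-horizon patients carry no
label information and zero-labeling them would bias the negative class.
Months convert to days at 30.44 d/month.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .imgio import ClinicalRecord
from .tsr import TSRReport

log = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.44

__all__ = [
    "SurvivalDataset",
    "KMCurve",
    "select_slide",
    "make_horizon_labels",
    "cv_auc",
    "km_estimate",
    "stratify_by_mean",
    "DAYS_PER_MONTH",
]


@dataclass
class SurvivalDataset:
    """Feature matrix plus horizon labels for the included patients."""

    features: pd.DataFrame  # one row per included patient
    labels: np.ndarray  # 1 = dead within horizon, 0 = survived past it
    patient_ids: list[str]
    horizon_days: int
    n_excluded: int  # censored before the horizon
    survival_days: np.ndarray
    events: np.ndarray


@dataclass
class KMCurve:
    group: str
    times: np.ndarray  # event/censoring times in days, ordered
    survival: np.ndarray  # product-limit estimate at each time
    at_risk: np.ndarray
    n_events: np.ndarray
    threshold: float | None = None

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def select_slide(
    reports_by_patient: Mapping[str, Sequence[TSRReport]],
) -> dict[str, TSRReport]:
    """Per patient, the slide with the highest TSR; ties go to the
    lexicographically first slide id (logged)."""
    chosen: dict[str, TSRReport] = {}
    for pid, reports in reports_by_patient.items():
        if not reports:
            raise ValueError(f"patient {pid}: no TSR reports")
        best = sorted(reports, key=lambda r: (-r.tsr, r.slide_id))[0]
        ties = [r.slide_id for r in reports if r.tsr == best.tsr]
        if len(ties) > 1:
            log.info("patient %s: TSR tie among %s -> %s", pid, ties, best.slide_id)
        chosen[pid] = best
    return chosen


def make_horizon_labels(
    records: Sequence[ClinicalRecord],
    horizon_months: float,
    tsr_by_patient: Mapping[str, float],
    covariates: Sequence[str] = ("age", "gender"),
) -> SurvivalDataset:
    """Build the horizon-classification dataset.

    Features are the TSR plus requested clinical covariates (categoricals
    one-hot encoded).  Standardization is NOT applied here — it is fit on
    training folds only inside :func:`cv_auc`.
    """
    horizon_days = int(round(DAYS_PER_MONTH * horizon_months))
    rows, labels, pids, days, events = [], [], [], [], []
    n_excluded = 0
    for r in records:
        if r.patient_id not in tsr_by_patient:
            continue
        if r.survival_days > horizon_days:
            y = 0
        elif r.event:
            y = 1
        else:  # censored before the horizon: no label information
            n_excluded += 1
            continue
        row = {"tsr": float(tsr_by_patient[r.patient_id])}
        for cov in covariates:
            row[cov] = getattr(r, cov)
        rows.append(row)
        labels.append(y)
        pids.append(r.patient_id)
        days.append(r.survival_days)
        events.append(r.event)
    if not rows:
        raise ValueError(f"all patients excluded at horizon {horizon_months} months")
    df = pd.DataFrame(rows)
    df = pd.get_dummies(df, dtype=float)
    return SurvivalDataset(
        features=df,
        labels=np.asarray(labels, dtype=int),
        patient_ids=pids,
        horizon_days=horizon_days,
        n_excluded=n_excluded,
        survival_days=np.asarray(days, dtype=float),
        events=np.asarray(events, dtype=bool),
    )


def cv_auc(
    dataset: SurvivalDataset,
    k: int = 5,
    seed: int = 0,
    l2_C: float = 1.0,
) -> dict:
    """Stratified k-fold logistic regression AUC.

    Feature scaling and the model are fit on training folds only; reported
    as per-fold AUCs, mean +/- SD, and a pooled out-of-fold ROC curve.
    """
    X = dataset.features.to_numpy(dtype=float)
    y = dataset.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"minority class has {counts.min()} patients; cannot stratify {k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_aucs = []
    pooled_scores = np.zeros(len(y))
    for train_idx, test_idx in skf.split(X, y):
        model = make_pipeline(
            StandardScaler(), LogisticRegression(C=l2_C, max_iter=2000)
        )
        model.fit(X[train_idx], y[train_idx])
        scores = model.predict_proba(X[test_idx])[:, 1]
        pooled_scores[test_idx] = scores
        fold_aucs.append(roc_auc_score(y[test_idx], scores))
    fpr, tpr, thresholds = roc_curve(y, pooled_scores)
    return {
        "fold_aucs": [float(a) for a in fold_aucs],
        "mean_auc": float(np.mean(fold_aucs)),
        "sd_auc": float(np.std(fold_aucs)),
        "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                "thresholds": thresholds.tolist()},
        "horizon_days": dataset.horizon_days,
        "n": len(y),
        "n_excluded": dataset.n_excluded,
    }


def stratify_by_mean(tsr_values: Mapping[str, float]) -> tuple[dict[str, str], float]:
    """High/low risk groups split at the cohort-mean TSR (threshold logged)."""
    threshold = float(np.mean(list(tsr_values.values())))
    log.info("KM stratification threshold (mean TSR) = %.4f", threshold)
    groups = {
        pid: ("high" if v > threshold else "low") for pid, v in tsr_values.items()
    }
    return groups, threshold


def km_estimate(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str],
    threshold: float | None = None,
) -> tuple[list[KMCurve], float]:
    """Product-limit survival curves per group plus the log-rank p-value."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if times.size == 0:
        raise ValueError("empty group: no survival times given")
    if np.any(times < 0):
        raise ValueError("negative survival times")
    curves = []
    for g in sorted(set(groups.tolist())):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(g))
        # report at distinct observed times, skipping the t=0 anchor row
        t = kmf.survival_function_.index.to_numpy()
        s = kmf.survival_function_[str(g)].to_numpy()
        keep = t > 0
        ev = kmf.event_table
        curves.append(
            KMCurve(
                group=str(g),
                times=t[keep],
                survival=s[keep],
                at_risk=ev["at_risk"].to_numpy()[np.isin(ev.index.to_numpy(), t[keep])],
                n_events=ev["observed"].to_numpy()[np.isin(ev.index.to_numpy(), t[keep])],
                threshold=threshold,
            )
        )
    if len(set(groups.tolist())) < 2:
        return curves, float("nan")
    res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.p_value)
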