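import numpy as np
import pytest

from stromascope.imgio import ClinicalRecord
from stromascope.survival import (
    DAYS_PER_MONTH,
    cv_auc,
    km_estimate,
    make_horizon_labels,
    select_slide,
    stratify_by_mean,
)
from stromascope.synthdata import CohortRecipe, generate_cohort
from stromascope.tsr import TSRReport


def _report(slide_id, tsr):
    return TSRReport(slide_id, 10.0, 10.0, 100.0, tsr=tsr)


class TestSelectSlide:
    def test_single_slide(self):
        r = _report("s1", 0.4)
        assert select_slide({"P1": [r]})["P1"] is r

    def test_highest_wins(self):
        chosen = select_slide({"P1": [_report("a", 0.4), _report("b", 0.9)]})
        assert chosen["P1"].slide_id == "b"

    def test_tie_lexicographic(self):
        chosen = select_slide({"P1": [_report("zz", 0.5), _report("aa", 0.5)]})
        assert chosen["P1"].slide_id == "aa"

    def test_no_reports_raises(self):
        with pytest.raises(ValueError):
            select_slide({"P1": []})


def _rec(pid, status, days, age=60.0, gender="female"):
    return ClinicalRecord(pid, age, gender, status, days)


class TestHorizonLabels:
    TSR = {"P1": 0.5, "P2": 0.6, "P3": 0.7}

    def test_dead_within_horizon(self):
        ds = make_horizon_labels([_rec("P1", "dead", 100)], 6, self.TSR)
        assert ds.horizon_days == round(6 * DAYS_PER_MONTH) == 183
        assert list(ds.labels) == [1]

    def test_alive_beyond_horizon(self):
        ds = make_horizon_labels([_rec("P1", "alive", 400)], 6, self.TSR)
        assert list(ds.labels) == [0]

    def test_censored_before_horizon_excluded(self):
        ds = make_horizon_labels(
            [_rec("P1", "alive", 90), _rec("P2", "dead", 50)], 6, self.TSR
        )
        assert ds.patient_ids == ["P2"]
        assert ds.n_excluded == 1

    def test_dead_beyond_horizon_is_negative(self):
        ds = make_horizon_labels([_rec("P1", "dead", 400)], 6, self.TSR)
        assert list(ds.labels) == [0]

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            make_horizon_labels([_rec("P1", "alive", 10)], 6, self.TSR)

    def test_exclusion_only_changes_that_group(self):
        base = [
            _rec("P1", "dead", 50),
            _rec("P2", "alive", 400),
            _rec("P3", "alive", 90),  # censored before horizon
        ]
        ds = make_horizon_labels(base, 6, self.TSR)
        assert set(ds.patient_ids) == {"P1", "P2"}
        # the labels of the retained patients match the no-exclusion rule
        assert dict(zip(ds.patient_ids, ds.labels)) == {"P1": 1, "P2": 0}

    def test_one_hot_covariates(self):
        recs = [
            _rec("P1", "dead", 50, gender="female"),
            _rec("P2", "dead", 300, gender="male"),
        ]
        ds = make_horizon_labels(recs, 12, self.TSR)
        assert any(c.startswith("gender_") for c in ds.features.columns)
        assert "tsr" in ds.features.columns


class TestCvAuc:
    def _dataset(self, x, y):
        import pandas as pd

        from stromascope.survival import SurvivalDataset

        return SurvivalDataset(
            features=pd.DataFrame({"tsr": x}),
            labels=np.asarray(y),
            patient_ids=[f"P{i}" for i in range(len(y))],
            horizon_days=183,
            n_excluded=0,
            survival_days=np.zeros(len(y)),
            events=np.asarray(y, bool),
        )

    def test_perfectly_separating_feature(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        x = y + rng.uniform(-0.4, 0.4, 100)
        res = cv_auc(self._dataset(x, y), k=5, seed=0)
        assert all(a == 1.0 for a in res["fold_aucs"])

    def test_null_feature_auc_near_half(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 500)
        x = rng.normal(size=500)
        res = cv_auc(self._dataset(x, y), k=5, seed=0)
        assert 0.4 <= res["mean_auc"] <= 0.6

    def test_minority_too_small_raises(self):
        y = [1] * 3 + [0] * 50
        x = np.arange(53.0)
        with pytest.raises(ValueError, match="minority"):
            cv_auc(self._dataset(x, y), k=5)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        x = y * 0.8 + rng.normal(scale=0.7, size=200)
        r1 = cv_auc(self._dataset(x, y), k=5, seed=3)
        r2 = cv_auc(self._dataset(np.exp(3 * x), y, ), k=5, seed=3)
        # logistic regression on a monotone-transformed single feature keeps
        # the ranking, so per-fold AUCs agree
        assert np.allclose(sorted(r1["fold_aucs"]), sorted(r2["fold_aucs"]), atol=0.05)


class TestKaplanMeier:
    def test_no_censoring_closed_form(self):
        curves, _ = km_estimate([1, 2, 3, 4], [1, 1, 1, 1], ["g"] * 4)
        c = curves[0]
        assert np.allclose(c.survival, [0.75, 0.5, 0.25, 0.0])

    @staticmethod
    def product_limit_oracle(times, events):
        """Hand product-limit: S(t) = prod over distinct event times t_i <= t
        of (1 - d_i / n_i), with n_i = subjects whose time >= t_i."""
        times = np.asarray(times, float)
        events = np.asarray(events, bool)
        out = {}
        s = 1.0
        for t in np.unique(times):
            n_i = (times >= t).sum()
            d_i = ((times == t) & events).sum()
            s *= 1.0 - d_i / n_i
            out[float(t)] = s
        return out

    def test_censored_toy_product_limit(self):
        # times {6,6,6,7,10}, events {1,1,0,1,0}:
        # S(6) = 1 - 2/5 = 0.6
        # at t=7 the risk set is {7, 10} (two deaths and one censoring left
        # at 6), so S(7) = 0.6 * (1 - 1/2) = 0.3
        times, events = [6, 6, 6, 7, 10], [1, 1, 0, 1, 0]
        oracle = self.product_limit_oracle(times, events)
        assert oracle[6.0] == pytest.approx(0.6)
        assert oracle[7.0] == pytest.approx(0.3)
        curves, _ = km_estimate(times, events, ["g"] * 5)
        c = curves[0]
        assert c.survival_at(6) == pytest.approx(0.6)
        assert c.survival_at(7) == pytest.approx(0.3)
        assert c.survival_at(10) == pytest.approx(oracle[10.0])

    def test_identical_groups_p_one(self):
        times = [3, 5, 8, 12, 20] * 2
        events = [1, 1, 0, 1, 1] * 2
        groups = ["a"] * 5 + ["b"] * 5
        _, p = km_estimate(times, events, groups)
        assert p == pytest.approx(1.0)

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 50, 40)
        curves, _ = km_estimate(times, [1] * 40, ["g"] * 40)
        c = curves[0]
        for t, s in zip(c.times, c.survival):
            assert s == pytest.approx((times > t).mean())

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(4)
        times = rng.integers(1, 100, 60)
        events = rng.integers(0, 2, 60)
        curves, _ = km_estimate(times, events, ["g"] * 60)
        s = curves[0].survival
        assert (np.diff(s) <= 1e-12).all()
        assert (s >= 0).all() and (s <= 1).all()

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            km_estimate([], [], [])

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1], ["a", "a"])


class TestStratifyByMean:
    def test_threshold_is_mean(self):
        groups, thr = stratify_by_mean({"P1": 0.2, "P2": 0.8})
        assert thr == pytest.approx(0.5)
        assert groups == {"P1": "low", "P2": "high"}


class TestSurvivalOnCohort:
    def test_effect_gives_auc_above_chance(self):
        records, recipes = generate_cohort(CohortRecipe(n_patients=200, beta=3.0, seed=5))
        tsr = {r.patient_id: rec.target_stroma_fraction for r, rec in zip(records, recipes)}
        ds = make_horizon_labels(records, 6, tsr)
        res = cv_auc(ds, k=5, seed=0)
        assert res["mean_auc"] > 0.6

    def test_higher_tsr_higher_risk_direction(self):
        records, recipes = generate_cohort(CohortRecipe(n_patients=200, beta=3.0, seed=5))
        tsr = {r.patient_id: rec.target_stroma_fraction for r, rec in zip(records, recipes)}
        groups, thr = stratify_by_mean(tsr)
        curves, p = km_estimate(
            [r.survival_days for r in records],
            [r.event for r in records],
            [groups[r.patient_id] for r in records],
            thr,
        )
        assert p < 0.05
        by_group = {c.group: c for c in curves}
        t_mid = np.median([r.survival_days for r in records])
        assert by_group["high"].survival_at(t_mid) < by_group["low"].survival_at(t_mid)
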