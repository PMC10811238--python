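"""Evaluation statistics: AUC, DeLong, NRI/IDI, decision curves, protocols."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedrad.evalstats import (
    ScoredSet,
    clinical_baseline,
    confusion_metrics,
    decision_curve,
    delong_test,
    idi,
    nri,
    roc_auc,
    threefold_cv,
    youden_threshold,
)


def _pair_count_auc(scores, labels):
    """Independent oracle: concordant pairs / all pos-neg pairs, ties half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        s = ScoredSet(scores=np.array([0.1, 0.4, 0.35, 0.8]), labels=np.array([0, 0, 1, 1]))
        _, auc = roc_auc(s)
        assert abs(auc - 0.75) < 1e-12

    def test_perfect_and_tied_scores(self):
        y = np.array([0, 1, 0, 1])
        assert roc_auc(ScoredSet(scores=y.astype(float), labels=y))[1] == 1.0
        assert roc_auc(ScoredSet(scores=np.full(4, 0.5), labels=y))[1] == 0.5

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_pair_counting_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(6, 40))
        y = np.zeros(n, dtype=int)
        y[: max(1, int(r.integers(1, n)))] = 1
        r.shuffle(y)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        scores = np.round(r.uniform(size=n), 2)  # rounding induces ties
        _, auc = roc_auc(ScoredSet(scores=scores, labels=y))
        assert abs(auc - _pair_count_auc(scores, y)) < 1e-10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(ScoredSet(scores=np.array([0.1, 0.9]), labels=np.array([1, 1])))


class TestConfusionMetrics:
    def test_perfect_scores(self):
        y = np.array([0, 1, 0, 1])
        m = confusion_metrics(ScoredSet(scores=y.astype(float), labels=y), 0.5)
        for k in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            assert m[k] == 1.0

    def test_all_negative_predictions(self):
        y = np.array([1, 1, 0, 0, 0])
        m = confusion_metrics(ScoredSet(scores=np.zeros(5), labels=y), 0.5)
        assert m["sensitivity"] == 0.0
        assert np.isnan(m["ppv"])  # no positive predictions
        assert abs(m["npv"] - 0.6) < 1e-12  # 1 - prevalence

    def test_published_count_arithmetic(self):
        """The metric formulas reproduce printed sensitivity/specificity from
        their 2x2 counts: 52/71 events detected, 166/183 non-events excluded."""
        scores = np.concatenate([np.ones(52), np.zeros(19), np.ones(17), np.zeros(166)])
        labels = np.concatenate([np.ones(71, dtype=int), np.zeros(183, dtype=int)])
        m = confusion_metrics(ScoredSet(scores=scores, labels=labels), 0.5)
        assert abs(m["sensitivity"] - 52 / 71) < 1e-12
        assert abs(m["specificity"] - 166 / 183) < 1e-12
        assert round(m["sensitivity"], 3) == 0.732
        assert round(m["specificity"], 3) == 0.907


class TestDeLong:
    def test_identical_scores_p_one(self, rng):
        y = np.array([0, 1] * 10)
        s = rng.uniform(size=20)
        diff, var, p = delong_test(ScoredSet(scores=s, labels=y), ScoredSet(scores=s.copy(), labels=y))
        assert diff == 0.0 and p == 1.0

    def test_small_case_matches_hand_structural_components(self):
        """n=6: V10/V01 components computed by direct pair counting."""
        y = np.array([1, 1, 1, 0, 0, 0])
        s1 = np.array([0.9, 0.7, 0.3, 0.6, 0.2, 0.1])
        s2 = np.array([0.8, 0.5, 0.4, 0.7, 0.3, 0.2])

        def components(s):
            pos, neg = s[y == 1], s[y == 0]
            v10 = np.array([np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for n in neg])
                            for p in pos])
            v01 = np.array([np.mean([1.0 if p > n else 0.5 if p == n else 0.0 for p in pos])
                            for n in neg])
            return v10, v01

        v10_1, v01_1 = components(s1)
        v10_2, v01_2 = components(s2)
        m = n = 3
        s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1)
        s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1)
        expected_var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
        _, var, _ = delong_test(ScoredSet(scores=s1, labels=y), ScoredSet(scores=s2, labels=y))
        assert abs(var - expected_var) < 1e-12

    def test_p_close_to_paired_bootstrap(self):
        """DeLong p agrees with a 10,000-rep paired bootstrap within 0.03."""
        r = np.random.default_rng(42)
        n = 100
        y = np.repeat([0, 1], n // 2)
        base = r.normal(size=n) + y
        s1 = 1 / (1 + np.exp(-(base + 0.4 * r.normal(size=n))))
        s2 = 1 / (1 + np.exp(-(base + 0.7 * r.normal(size=n))))
        diff, _, p = delong_test(ScoredSet(scores=s1, labels=y), ScoredSet(scores=s2, labels=y))

        boots = []
        for _ in range(10_000):
            idx = r.integers(0, n, size=n)
            yy = y[idx]
            if yy.min() == yy.max():
                continue
            boots.append(_pair_count_auc(s1[idx], yy) - _pair_count_auc(s2[idx], yy))
        boots = np.asarray(boots)
        se = boots.std(ddof=1)
        from scipy import stats as sps

        p_boot = 2 * sps.norm.sf(abs(diff) / se)
        assert abs(p - p_boot) < 0.03


class TestNriIdi:
    def test_no_change_is_zero(self, rng):
        y = rng.integers(0, 2, size=20)
        s = rng.uniform(size=20)
        assert nri(s, s, y) == 0.0
        assert idi(s, s, y) == 0.0

    def test_maximum_nri(self):
        y = np.array([1, 1, 0, 0])
        old = np.array([0.5, 0.5, 0.5, 0.5])
        new = np.array([0.9, 0.8, 0.1, 0.2])
        assert nri(old, new, y) == 2.0

    def test_worked_examples(self):
        y = np.array([1, 1, 0, 0])
        old = np.array([0.6, 0.4, 0.5, 0.5])
        new = np.array([0.8, 0.6, 0.3, 0.1])
        assert nri(old, new, y) == 2.0
        assert abs(idi(old, new, y) - 0.5) < 1e-12

    def test_idi_antisymmetry(self, rng):
        y = np.array([0, 1] * 8)
        a, b = rng.uniform(size=16), rng.uniform(size=16)
        assert abs(idi(a, b, y) + idi(b, a, y)) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(4, 30))
        y = r.integers(0, 2, size=n)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        a, b = r.uniform(size=n), r.uniform(size=n)
        assert -2.0 <= nri(a, b, y) <= 2.0
        assert -1.0 <= idi(a, b, y) <= 1.0


class TestDecisionCurve:
    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.array([1, 1, 0, 0, 0])
        df = decision_curve(ScoredSet(scores=y.astype(float), labels=y),
                            thresholds=np.array([0.1, 0.3, 0.5, 0.7]))
        assert np.allclose(df["net_benefit"], 0.4)

    def test_treat_all_zero_at_prevalence(self):
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])  # prevalence 0.2
        df = decision_curve(ScoredSet(scores=np.full(10, 0.5), labels=y),
                            thresholds=np.array([0.2]))
        assert abs(df["treat_all"].iloc[0]) < 1e-12
        assert df["treat_none"].iloc[0] == 0.0

    def test_toy_hand_counted(self):
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        scores = np.array([0.9, 0.6, 0.1, 0.8, 0.3, 0.1, 0.05, 0.02, 0.4, 0.15])
        df = decision_curve(ScoredSet(scores=scores, labels=y), thresholds=np.array([0.2]))
        # at pt=0.2: predicted positive = scores >= 0.2 -> TP = 2, FP = 3
        expected = 2 / 10 - (3 / 10) * (0.2 / 0.8)
        assert abs(df["net_benefit"].iloc[0] - expected) < 1e-12

    def test_model_net_benefit_bounded_by_prevalence(self, rng):
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        s = rng.uniform(size=50)
        df = decision_curve(ScoredSet(scores=s, labels=y))
        assert np.all(df["net_benefit"] <= y.mean() + 1e-12)

    def test_default_grid_is_99_points(self, rng):
        y = np.array([0, 1] * 5)
        df = decision_curve(ScoredSet(scores=rng.uniform(size=10), labels=y))
        assert len(df) == 99

    def test_threshold_one_rejected(self):
        y = np.array([0, 1])
        with pytest.raises(ValueError):
            decision_curve(ScoredSet(scores=np.array([0.1, 0.9]), labels=y),
                           thresholds=np.array([1.0]))


class TestThreefoldCV:
    def _fit_predict(self, Xtr, ytr, Xte):
        mu1 = Xtr[ytr == 1].mean(axis=0)
        mu0 = Xtr[ytr == 0].mean(axis=0)
        d = Xte @ (mu1 - mu0)
        return 1 / (1 + np.exp(-d))

    def test_stratified_fold_sizes(self, rng):
        X = rng.normal(size=(9, 2))
        y = np.array([1] * 6 + [0] * 3)
        out = threefold_cv(X, y, self._fit_predict, seed=0)
        for tr_idx, te_idx in out["folds"]:
            assert len(te_idx) == 3
            assert (y[te_idx] == 1).sum() == 2 and (y[te_idx] == 0).sum() == 1

    def test_folds_partition_everything(self, rng):
        X = rng.normal(size=(30, 3))
        y = np.array([0, 1] * 15)
        out = threefold_cv(X, y, self._fit_predict, seed=1)
        all_test = np.concatenate([te for _, te in out["folds"]])
        assert sorted(all_test) == list(range(30))

    def test_deterministic_pipeline_reproduces(self, rng):
        X = rng.normal(size=(30, 3)) + np.array([0, 1] * 15)[:, None]
        y = np.array([0, 1] * 15)
        a = threefold_cv(X, y, self._fit_predict, seed=2)
        b = threefold_cv(X, y, self._fit_predict, seed=2)
        assert a["fold_aucs"] == b["fold_aucs"]

    def test_rare_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError):
            threefold_cv(X, y, self._fit_predict, seed=0)


class TestClinicalBaseline:
    def _frame(self, rng, n):
        from fedrad.cohort import N_STAGES, T_STAGES

        return pd.DataFrame({
            "t_stage": rng.choice(T_STAGES, size=n),
            "n_stage": rng.choice(N_STAGES, size=n),
            "ca199": rng.choice(["absent", "present"], size=n),
        })

    def test_null_covariates_give_chance_auc(self, rng):
        n = 400
        df = self._frame(rng, n)
        y = rng.integers(0, 2, size=n)
        scores = clinical_baseline(df, y, seed=0)
        _, auc = roc_auc(ScoredSet(scores=scores, labels=y))
        assert abs(auc - 0.5) < 0.05

    def test_deterministic_t_stage_signal_detected(self, rng):
        n = 300
        df = self._frame(rng, n)
        y = (df["t_stage"].astype(int) >= 3).astype(int).to_numpy()
        scores = clinical_baseline(df, y, seed=0)
        _, auc = roc_auc(ScoredSet(scores=scores, labels=y))
        assert auc >= 0.95

    def test_deterministic_given_seed(self, rng):
        df = self._frame(rng, 60)
        y = rng.integers(0, 2, size=60)
        a = clinical_baseline(df, y, seed=5)
        b = clinical_baseline(df, y, seed=5)
        assert np.array_equal(a, b)

    def test_missing_covariates_rejected(self, rng):
        df = self._frame(rng, 10).drop(columns=["ca199"])
        with pytest.raises(ValueError):
            clinical_baseline(df, rng.integers(0, 2, size=10))


def test_youden_threshold_on_separable_scores():
    y = np.array([0, 0, 0, 1, 1, 1])
    s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    t = youden_threshold(ScoredSet(scores=s, labels=y))
    assert 0.3 < t <= 0.7


class TestCategoricalNri:
    def test_category_jumps_counted(self):
        from fedrad.evalstats import nri_categorical

        y = np.array([1, 1, 0, 0])
        old = np.array([0.1, 0.1, 0.5, 0.5])
        new = np.array([0.5, 0.9, 0.1, 0.1])  # both events up, both nonevents down
        assert nri_categorical(old, new, y, cutoffs=[1 / 3, 2 / 3]) == 2.0

    def test_within_category_movement_ignored(self):
        from fedrad.evalstats import nri_categorical

        y = np.array([1, 0])
        old = np.array([0.40, 0.60])
        new = np.array([0.45, 0.55])  # moves, but stays in the middle category
        assert nri_categorical(old, new, y, cutoffs=[1 / 3, 2 / 3]) == 0.0

    def test_bad_cutoffs_rejected(self):
        from fedrad.evalstats import nri_categorical

        with pytest.raises(ValueError):
            nri_categorical([0.1], [0.2], [1], cutoffs=[0.6, 0.4])
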