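"""Evaluation statistics for paired clinical risk models.

ROC/AUC and confusion metrics, the DeLong test for correlated AUCs,
continuous (category-free) NRI and IDI, decision-curve analysis, stratified
threefold cross-validation, a permutation-robustness protocol, and a
random-forest clinical baseline over T-stage, N-stage and CA199 status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "ScoredSet",
    "ComparisonResult",
    "roc_auc",
    "confusion_metrics",
    "delong_test",
    "subgroup_auc_comparison",
    "nri",
    "nri_categorical",
    "idi",
    "bootstrap_p",
    "compare_models",
    "decision_curve",
    "threefold_cv",
    "permutation_robustness",
    "clinical_baseline",
    "youden_threshold",
]


@dataclass
class ScoredSet:
    scores: np.ndarray
    labels: np.ndarray
    group_keys: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.labels = np.asarray(self.labels).astype(int)
        if len(self.scores) != len(self.labels):
            raise ValueError("scores and labels lengths differ")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")


@dataclass
class ComparisonResult:
    auc_1: float
    auc_2: float
    delong_p: float
    nri: float
    idi: float
    nri_p: float | None = None
    idi_p: float | None = None


# ---------------------------------------------------------------------------
# ROC / confusion


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")


def roc_auc(scored: ScoredSet) -> tuple[np.ndarray, float]:
    """ROC curve points (fpr, tpr per threshold) and trapezoidal AUC.

    The trapezoidal AUC over unique thresholds equals the rank statistic
    U / (n1 * n2) with tied pairs counted half.
    """
    _check_two_classes(scored.labels)
    fpr, tpr, _ = roc_curve(scored.labels, scored.scores)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def confusion_metrics(scored: ScoredSet, threshold: float = 0.5) -> dict[str, float]:
    """Sensitivity/specificity/accuracy/PPV/NPV at a probability threshold.

    Zero-denominator metrics come back as NaN."""
    if not (0 <= threshold <= 1):
        raise ValueError("threshold must be in [0, 1]")
    pred = scored.scores >= threshold
    y = scored.labels.astype(bool)
    tp = int(np.sum(pred & y))
    fp = int(np.sum(pred & ~y))
    tn = int(np.sum(~pred & ~y))
    fn = int(np.sum(~pred & y))

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, tp + fp + tn + fn),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
    }


def youden_threshold(scored: ScoredSet) -> float:
    """Threshold maximizing sensitivity + specificity - 1."""
    fpr, tpr, thr = roc_curve(scored.labels, scored.scores)
    j = tpr - fpr
    return float(np.clip(thr[np.argmax(j)], 0.0, 1.0))


# ---------------------------------------------------------------------------
# DeLong test for two correlated AUCs


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """Structural components (V10 per event, V01 per non-event) and the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_test(scored_1: ScoredSet, scored_2: ScoredSet) -> tuple[float, float, float]:
    """DeLong's test for the difference of two correlated AUCs.

    Returns (auc1 - auc2, variance of the difference, two-tailed p).  Two
    identical score vectors give difference 0 and p = 1 by convention.
    """
    if not np.array_equal(scored_1.labels, scored_2.labels):
        raise ValueError("paired scores require identical labels")
    _check_two_classes(scored_1.labels)
    y = scored_1.labels
    auc1, v10_1, v01_1 = _delong_components(scored_1.scores, y)
    auc2, v10_2, v01_2 = _delong_components(scored_2.scores, y)
    m, n = len(v10_1), len(v01_1)
    s10 = np.cov(np.stack([v10_1, v10_2]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.stack([v01_1, v01_2]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc1 - auc2
    if var <= 0:
        return float(diff), float(max(var, 0.0)), 1.0 if np.isclose(diff, 0) else 0.0
    z = diff / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(diff), float(var), float(p)


def subgroup_auc_comparison(scored: ScoredSet, by: str) -> pd.DataFrame:
    """Does performance depend on a patient characteristic (e.g. sex, age band)?

    Splits the scored set by a ``group_keys`` column, computes each
    subgroup's AUC with its DeLong structural-component variance, and tests
    every subgroup pair with an independent-samples z-test.  Large p-values
    indicate performance is not driven by that characteristic.
    """
    if scored.group_keys is None or by not in scored.group_keys.columns:
        raise ValueError(f"group_keys must contain column '{by}'")
    groups = {}
    for val in scored.group_keys[by].unique():
        mask = (scored.group_keys[by] == val).to_numpy()
        y = scored.labels[mask]
        if len(np.unique(y)) < 2:
            continue
        auc, v10, v01 = _delong_components(scored.scores[mask], y)
        var = (np.var(v10, ddof=1) / len(v10) if len(v10) > 1 else 0.0) \
            + (np.var(v01, ddof=1) / len(v01) if len(v01) > 1 else 0.0)
        groups[val] = (auc, var, int(mask.sum()))
    rows = []
    keys = list(groups)
    for i in range(len(keys)):
        for j in range(i + 1, len(keys)):
            (a1, var1, n1), (a2, var2, n2) = groups[keys[i]], groups[keys[j]]
            var = var1 + var2
            if var > 0:
                p = float(2 * stats.norm.sf(abs(a1 - a2) / np.sqrt(var)))
            else:
                p = 1.0 if np.isclose(a1, a2) else 0.0
            rows.append(dict(group_a=keys[i], group_b=keys[j], auc_a=a1, auc_b=a2,
                             n_a=n1, n_b=n2, p_value=p))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NRI / IDI


def nri(old_scores, new_scores, labels) -> float:
    """Continuous (category-free) net reclassification improvement.

    [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)],
    bounded in [-2, 2]."""
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    up = new > old
    down = new < old
    ev = y == 1
    ne = ~ev
    p_up_e = up[ev].mean() if ev.any() else 0.0
    p_dn_e = down[ev].mean() if ev.any() else 0.0
    p_up_n = up[ne].mean() if ne.any() else 0.0
    p_dn_n = down[ne].mean() if ne.any() else 0.0
    return float((p_up_e - p_dn_e) + (p_dn_n - p_up_n))


def nri_categorical(old_scores, new_scores, labels, cutoffs) -> float:
    """Categorical NRI over user-supplied risk-category cutoffs.

    Scores are binned by ``cutoffs`` (ascending, strictly inside (0, 1));
    up/down movements are category changes rather than any score change."""
    cutoffs = np.asarray(cutoffs, dtype=float)
    if cutoffs.size == 0 or np.any(np.diff(cutoffs) <= 0):
        raise ValueError("cutoffs must be non-empty and strictly increasing")
    old_cat = np.digitize(np.asarray(old_scores, dtype=float), cutoffs)
    new_cat = np.digitize(np.asarray(new_scores, dtype=float), cutoffs)
    return nri(old_cat, new_cat, labels)


def idi(old_scores, new_scores, labels) -> float:
    """Integrated discrimination improvement:
    (mean new|event - mean new|nonevent) - (mean old|event - mean old|nonevent)."""
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    ev = y == 1
    ne = ~ev
    return float((new[ev].mean() - new[ne].mean()) - (old[ev].mean() - old[ne].mean()))


def bootstrap_p(stat_fn, old_scores, new_scores, labels, n_boot: int = 1000, seed: int = 0) -> float:
    """Two-sided bootstrap p-value for a paired improvement statistic, from
    the normal approximation to its resampling distribution."""
    old = np.asarray(old_scores, dtype=float)
    new = np.asarray(new_scores, dtype=float)
    y = np.asarray(labels).astype(int)
    rng = np.random.default_rng(seed)
    obs = stat_fn(old, new, y)
    vals = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        vals.append(stat_fn(old[idx], new[idx], y[idx]))
    se = np.std(vals, ddof=1)
    if se == 0:
        return 1.0 if np.isclose(obs, 0) else 0.0
    return float(2 * stats.norm.sf(abs(obs) / se))


def compare_models(old: ScoredSet, new: ScoredSet, n_boot: int = 1000, seed: int = 0) -> ComparisonResult:
    """Full paired comparison: AUCs, DeLong p, NRI and IDI with bootstrap p."""
    _, auc_old = roc_auc(old)
    _, auc_new = roc_auc(new)
    _, _, p = delong_test(new, old)
    y = old.labels
    return ComparisonResult(
        auc_1=auc_new,
        auc_2=auc_old,
        delong_p=p,
        nri=nri(old.scores, new.scores, y),
        idi=idi(old.scores, new.scores, y),
        nri_p=bootstrap_p(nri, old.scores, new.scores, y, n_boot, seed),
        idi_p=bootstrap_p(idi, old.scores, new.scores, y, n_boot, seed + 1),
    )


# ---------------------------------------------------------------------------
# Decision-curve analysis


def decision_curve(scored: ScoredSet, thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Net benefit NB(pt) = TP/n - (FP/n) * pt/(1-pt) for the model, plus the
    treat-all and treat-none references, across threshold probabilities."""
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)  # 99 points over (0, 1)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any((thresholds <= 0) | (thresholds >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    y = scored.labels
    n = len(y)
    prev = y.mean()
    rows = []
    for pt in thresholds:
        pred = scored.scores >= pt
        tp = np.sum(pred & (y == 1)) / n
        fp = np.sum(pred & (y == 0)) / n
        w = pt / (1 - pt)
        rows.append(
            dict(
                threshold=pt,
                net_benefit=tp - fp * w,
                treat_all=prev - (1 - prev) * w,
                treat_none=0.0,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protocols


def threefold_cv(X: np.ndarray, y: np.ndarray, fit_predict, seed: int = 0) -> dict:
    """Stratified 3-fold cross-validation of a fit/predict callable.

    ``fit_predict(X_train, y_train, X_test) -> scores``.  Returns per-fold
    AUCs and their mean and sd."""
    y = np.asarray(y).astype(int)
    if len(y) < 6:
        raise ValueError("need at least 6 samples for stratified 3-fold CV")
    if min(np.bincount(y)) < 3:
        raise ValueError("each class needs >= 3 members to stratify 3 folds")
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=seed)
    aucs, folds = [], []
    for tr_idx, te_idx in skf.split(X, y):
        scores = fit_predict(X[tr_idx], y[tr_idx], X[te_idx])
        _, auc = roc_auc(ScoredSet(scores=scores, labels=y[te_idx]))
        aucs.append(auc)
        folds.append((tr_idx, te_idx))
    return {
        "fold_aucs": aucs,
        "mean_auc": float(np.mean(aucs)),
        "sd_auc": float(np.std(aucs, ddof=1)),
        "folds": folds,
    }


def permutation_robustness(train_cohorts, test_cohorts, pipeline, n_perms: int = 5, seed: int = 0) -> dict:
    """Shuffle training patients among centres and re-run the pipeline.

    ``pipeline(train_cohorts, test_cohorts, seed) -> per-centre test AUCs``.
    Reports each centre's mean +/- sd of AUC over the permutations (sd is 0,
    flagged, when n_perms == 1)."""
    from dataclasses import replace as _dc_replace

    if len(train_cohorts) < 2:
        raise ValueError("need at least 2 centres")
    rng = np.random.default_rng(seed)
    all_aucs = []
    for perm in range(n_perms):
        pool = [p for c in train_cohorts for p in c.patients]
        order = rng.permutation(len(pool))
        shuffled = []
        start = 0
        for cohort in train_cohorts:
            take = [pool[order[start + i]] for i in range(len(cohort.patients))]
            start += len(cohort.patients)
            shuffled.append(_dc_replace(cohort, patients=take))
        run_seed = int(rng.integers(2**31))
        all_aucs.append(pipeline(shuffled, test_cohorts, run_seed))
    arr = np.asarray(all_aucs)  # (n_perms, n_centres)
    return {
        "auc_mean": arr.mean(axis=0),
        "auc_sd": arr.std(axis=0, ddof=1) if n_perms > 1 else np.zeros(arr.shape[1]),
        "sd_defined": n_perms > 1,
        "all_aucs": arr,
    }


# ---------------------------------------------------------------------------
# Clinical baseline


def _encode_clinical(df: pd.DataFrame) -> np.ndarray:
    from .cohort import N_STAGES, T_STAGES

    req = ["t_stage", "n_stage", "ca199"]
    if any(c not in df.columns or df[c].isna().any() for c in req):
        raise ValueError(f"clinical covariates {req} must be present and complete")
    t = df["t_stage"].astype(str).map({s: i for i, s in enumerate(T_STAGES)})
    n = df["n_stage"].astype(str).map({s: i for i, s in enumerate(N_STAGES)})
    ca = df["ca199"].astype(str).map({"absent": 0, "present": 1})
    out = pd.concat([t, n, ca], axis=1).to_numpy(dtype=float)
    if np.isnan(out).any():
        raise ValueError("unrecognized clinical category codes")
    return out


def clinical_baseline(
    clinical: pd.DataFrame,
    labels: np.ndarray,
    n_estimators: int = 200,
    seed: int = 0,
    cv: int = 3,
) -> np.ndarray:
    """Random-forest risk scores from T-stage, N-stage and CA199 status.

    Returns out-of-fold probability scores (stratified ``cv``-fold) so the
    scores are honest for comparison statistics against an imaging model."""
    X = _encode_clinical(clinical)
    y = np.asarray(labels).astype(int)
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    if cv and cv > 1 and min(np.bincount(y)) >= cv:
        from sklearn.model_selection import cross_val_predict

        return cross_val_predict(rf, X, y, cv=StratifiedKFold(cv, shuffle=True, random_state=seed),
                                 method="predict_proba")[:, 1]
    rf.fit(X, y)
    return rf.predict_proba(X)[:, 1]
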