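"""Kernel-mean ("federated radiomic") features and their analysis.

Every convolution kernel of a trained model yields one feature per patient:
the spatial mean of that kernel's activation map.  The canonical model has
4449 kernels, hence 4449 features.  Downstream: a Mann-Whitney U filter
keeps class-discriminative features, greedy mRMR (mutual-information
difference criterion) reduces them to k (200 by default), and Pearson
correlations across centres split the survivors into *common* features
(correlated between centres — class signal shared everywhere) and
*adaptive* features (correlated only within their own centre).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.transform import resize as _sk_resize

from .model import LocalModel

__all__ = [
    "FeatureMatrix",
    "SelectionResult",
    "FeatureTaxonomy",
    "extract_features",
    "mann_whitney_filter",
    "exact_mwu_p",
    "mrmr_select",
    "select_features",
    "cross_centre_correlation",
    "classify_common_adaptive",
    "feature_euclidean_distance",
    "class_attention_map",
]


@dataclass
class FeatureMatrix:
    values: np.ndarray  # (patients, n_features)
    feature_ids: list[str]
    centre_id: str = ""
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.feature_ids):
            raise ValueError("feature_ids length must match column count")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains NaNs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_ids)

    def to_csv(self, path) -> None:
        df = self.to_frame()
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        df.insert(0, "centre", self.centre_id)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        centre = str(df.pop("centre").iloc[0]) if "centre" in df else ""
        labels = df.pop("label").to_numpy() if "label" in df else None
        return cls(values=df.to_numpy(dtype=float), feature_ids=list(df.columns),
                   centre_id=centre, labels=labels)


@dataclass
class SelectionResult:
    kept_ids: list[str]
    u_stats: np.ndarray | None = None
    p_values: np.ndarray | None = None
    mrmr_scores: np.ndarray | None = None
    k: int | None = None


@dataclass
class FeatureTaxonomy:
    common_ids: dict[str, list[str]]
    adaptive_ids: dict[str, list[str]]
    between_centre_corr: dict[str, np.ndarray] = field(default_factory=dict)
    within_centre_corr: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Feature extraction


def extract_features(model: LocalModel, images: np.ndarray, centre_id: str = "",
                     labels: np.ndarray | None = None) -> FeatureMatrix:
    """One feature per convolution kernel: the spatial mean of its activation.

    ``images`` must already be preprocessed to the model's input shape
    (N, 1, S, S).  Columns follow layer order, then channel index.
    """
    x = np.asarray(images, dtype=float)
    if x.ndim != 4 or x.shape[2] != model.config.input_size:
        raise ValueError(
            f"expected (N, 1, {model.config.input_size}, {model.config.input_size}) input"
        )
    model.set_capture(True)
    try:
        model.forward(x)
        cols, ids = [], []
        for name, conv in model.conv_modules():
            act = conv.last_output  # (N, C, H, W)
            cols.append(act.mean(axis=(2, 3)))
            ids.extend(f"{name}:ch{c}" for c in range(act.shape[1]))
    finally:
        model.set_capture(False)
    return FeatureMatrix(values=np.concatenate(cols, axis=1), feature_ids=ids,
                         centre_id=centre_id, labels=labels)


# ---------------------------------------------------------------------------
# Mann-Whitney filter

_EXACT_MAX_N = 10


def exact_mwu_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Tie-aware exact two-sided Mann-Whitney test by full enumeration.

    Enumerates every C(n1+n2, n1) assignment of the observed values to the
    two groups; the two-sided p-value is the null probability of a U at
    least as far from its midpoint n1*n2/2 as the observed one.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    mid = n1 * (n - n1) / 2
    dev_obs = abs(u_obs - mid)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mid) >= dev_obs - 1e-12:
            hits += 1
    return float(u_obs), hits / total


def mann_whitney_filter(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    alpha: float = 0.05,
) -> SelectionResult:
    """Two-sided per-feature U test; keeps features with p < alpha.

    Small samples (n1 + n2 <= 10) use the exact enumeration; larger samples
    use the tie-corrected normal approximation.
    """
    if isinstance(features, FeatureMatrix):
        values, ids = features.values, features.feature_ids
        labels = features.labels if labels is None else labels
    else:
        values = np.asarray(features, dtype=float)
        ids = [f"f{i}" for i in range(values.shape[1])]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("both classes with n >= 2 required")
    pos, neg = values[y == 1], values[y == 0]
    if len(pos) + len(neg) <= _EXACT_MAX_N:
        out = [exact_mwu_p(pos[:, j], neg[:, j]) for j in range(values.shape[1])]
        u = np.array([o[0] for o in out])
        p = np.array([o[1] for o in out])
    else:
        res = stats.mannwhitneyu(pos, neg, axis=0, method="asymptotic")
        u, p = np.asarray(res.statistic, dtype=float), np.asarray(res.pvalue, dtype=float)
    keep = p < alpha
    return SelectionResult(
        kept_ids=[ids[j] for j in np.nonzero(keep)[0]], u_stats=u, p_values=p
    )


# ---------------------------------------------------------------------------
# mRMR (greedy, MID criterion, quantile-binned mutual information)


def _quantile_bin(col: np.ndarray, bins: int) -> np.ndarray:
    qs = np.quantile(col, np.linspace(0, 1, bins + 1)[1:-1])
    return np.searchsorted(qs, col, side="right")


def _mi(a: np.ndarray, b: np.ndarray, na: int, nb: int) -> float:
    """Mutual information (nats) of two small integer-coded variables."""
    joint = np.bincount(a * nb + b, minlength=na * nb).astype(float).reshape(na, nb)
    n = joint.sum()
    pj = joint / n
    pa = pj.sum(axis=1, keepdims=True)
    pb = pj.sum(axis=0, keepdims=True)
    mask = pj > 0
    return float(np.sum(pj[mask] * np.log(pj[mask] / (pa @ pb)[mask])))


def mrmr_select(
    features: FeatureMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    k: int = 200,
    bins: int = 4,
) -> SelectionResult:
    """Greedy max-relevance min-redundancy selection (MID criterion).

    At each step adds ``argmax_f [I(f; y) - mean_{s in S} I(f; s)]`` over
    remaining candidates, with mutual information computed on quantile-binned
    features (ties broken by column index).  Requesting more features than
    available keeps everything.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(features, FeatureMatrix):
        values, ids = features.values, features.feature_ids
        labels = features.labels if labels is None else labels
    else:
        values = np.asarray(features, dtype=float)
        ids = [f"f{i}" for i in range(values.shape[1])]
    y = np.asarray(labels).astype(int)
    n, m = values.shape
    k = min(k, m)
    binned = np.stack([_quantile_bin(values[:, j], bins) for j in range(m)], axis=1)
    nb = int(binned.max()) + 1 if m else 1
    ny = int(y.max()) + 1
    relevance = np.array([_mi(binned[:, j], y, nb, ny) for j in range(m)])

    selected: list[int] = []
    red_sum = np.zeros(m)
    scores_out = []
    remaining = np.ones(m, dtype=bool)
    for _ in range(k):
        crit = relevance - (red_sum / len(selected) if selected else 0.0)
        crit = np.where(remaining, crit, -np.inf)
        j = int(np.argmax(crit))  # argmax takes the first max: index tie-break
        scores_out.append(crit[j])
        selected.append(j)
        remaining[j] = False
        new = binned[:, j]
        for c in np.nonzero(remaining)[0]:
            red_sum[c] += _mi(binned[:, c], new, nb, nb)
    return SelectionResult(
        kept_ids=[ids[j] for j in selected],
        mrmr_scores=np.array(scores_out),
        k=k,
    )


def select_features(
    features: FeatureMatrix,
    labels: np.ndarray | None = None,
    alpha: float = 0.05,
    k: int = 200,
) -> SelectionResult:
    """Full pipeline: Mann-Whitney filter, then mRMR down to k survivors."""
    mw = mann_whitney_filter(features, labels, alpha)
    idx = [features.feature_ids.index(i) for i in mw.kept_ids]
    if not idx:
        return SelectionResult(kept_ids=[], u_stats=mw.u_stats, p_values=mw.p_values, k=k)
    sub = FeatureMatrix(
        values=features.values[:, idx],
        feature_ids=mw.kept_ids,
        centre_id=features.centre_id,
        labels=features.labels,
    )
    mr = mrmr_select(sub, labels, k=k)
    return SelectionResult(
        kept_ids=mr.kept_ids,
        u_stats=mw.u_stats,
        p_values=mw.p_values,
        mrmr_scores=mr.mrmr_scores,
        k=k,
    )


# ---------------------------------------------------------------------------
# Common vs adaptive feature taxonomy


def _safe_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlations; zero-variance columns yield 0."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    denom = np.outer(sa, sb) * len(a)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a.T @ b) / denom
    return np.where(denom > 0, r, 0.0)


def cross_centre_correlation(feature_sets: list[FeatureMatrix]) -> tuple[dict, dict]:
    """Pearson correlations of selected feature columns within and across
    centres.  All sets must share the same sample axis (in practice: the
    pooled perturbed representative images pushed through each centre's
    model, so no raw data crosses centres)."""
    ns = {fs.values.shape[0] for fs in feature_sets}
    if len(ns) != 1:
        raise ValueError("feature sets must share a common sample axis")
    within = {fs.centre_id: _safe_corr(fs.values, fs.values) for fs in feature_sets}
    between = {}
    for i, a in enumerate(feature_sets):
        for j, b in enumerate(feature_sets):
            if i != j:
                between[(a.centre_id, b.centre_id)] = _safe_corr(a.values, b.values)
    return within, between


def classify_common_adaptive(
    feature_sets: list[FeatureMatrix],
    n_common: int = 5,
    n_adaptive: int = 5,
) -> FeatureTaxonomy:
    """Split each centre's features into common and adaptive sets.

    Per feature: the *between* score is the mean (over other centres) of its
    maximum absolute correlation with that centre's features; the *within*
    score is its maximum absolute correlation with its sibling features.
    The top ``n_common`` by between score become common; among the rest the
    top ``n_adaptive`` by (within - between) margin become adaptive, so the
    two sets are disjoint by construction.
    """
    within, between = cross_centre_correlation(feature_sets)
    common_ids, adaptive_ids = {}, {}
    bc_out, wc_out = {}, {}
    for fs in feature_sets:
        cid = fs.centre_id
        m = fs.values.shape[1]
        if n_common + n_adaptive > m:
            raise ValueError(f"centre {cid}: {n_common}+{n_adaptive} exceeds {m} features")
        w = np.abs(within[cid]).copy()
        np.fill_diagonal(w, 0.0)
        within_score = w.max(axis=1)
        others = [np.abs(between[(cid, o.centre_id)]).max(axis=1)
                  for o in feature_sets if o.centre_id != cid]
        between_score = np.mean(others, axis=0)
        order_common = np.argsort(-between_score, kind="stable")
        common = list(order_common[:n_common])
        margin = within_score - between_score
        rest = [j for j in np.argsort(-margin, kind="stable") if j not in common]
        adaptive = rest[:n_adaptive]
        common_ids[cid] = [fs.feature_ids[j] for j in common]
        adaptive_ids[cid] = [fs.feature_ids[j] for j in adaptive]
        bc_out[cid] = between_score
        wc_out[cid] = within_score
    return FeatureTaxonomy(
        common_ids=common_ids,
        adaptive_ids=adaptive_ids,
        between_centre_corr=bc_out,
        within_centre_corr=wc_out,
    )


def feature_euclidean_distance(
    taxonomy: FeatureTaxonomy, feature_sets: list[FeatureMatrix]
) -> dict[str, float]:
    """Mean pairwise Euclidean distance between standardized feature columns
    across centres, for the common group vs the adaptive group."""
    by_centre = {fs.centre_id: fs for fs in feature_sets}

    def _columns(ids_by_centre):
        cols = []
        for cid, ids in ids_by_centre.items():
            fs = by_centre[cid]
            for fid in ids:
                col = fs.values[:, fs.feature_ids.index(fid)].astype(float)
                sd = col.std()
                cols.append(((col - col.mean()) / sd) if sd > 0 else col * 0.0)
        return cols

    def _mean_dist(groups):
        dists = []
        centre_of = []
        cols = []
        for cid, ids in groups.items():
            for fid in ids:
                centre_of.append(cid)
            cols.extend(_columns({cid: ids}))
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                if centre_of[i] != centre_of[j]:
                    dists.append(np.linalg.norm(cols[i] - cols[j]))
        return float(np.mean(dists)) if dists else float("nan")

    return {
        "common_mean_distance": _mean_dist(taxonomy.common_ids),
        "adaptive_mean_distance": _mean_dist(taxonomy.adaptive_ids),
    }


# ---------------------------------------------------------------------------
# Class-attention visualization (gradient-weighted activation map)


def class_attention_map(model: LocalModel, image: np.ndarray, target_class: int = 1) -> np.ndarray:
    """Gradient-weighted attention over the last convolutional stage.

    Returns a heatmap in [0, 1] of the input's shape: channel activations of
    the final stage weighted by the spatially-pooled gradient of the target
    logit, ReLU'd, normalized and bilinearly upsampled.  A degenerate
    (all-zero) map falls back to a uniform 0.5 map.
    """
    x = np.asarray(image, dtype=float)
    if x.ndim == 2:
        x = x[None, None]
    last_conv = model.children[model.block_order[-1]].conv2
    model.set_capture(True)
    try:
        logits = model.forward(x)
        seed_grad = np.zeros_like(logits)
        seed_grad[:, target_class] = 1.0
        model.zero_grad()
        model.backward(seed_grad)
        act = last_conv.last_output[0]
        grad = last_conv.last_grad_out[0]
    finally:
        model.set_capture(False)
    weights = grad.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * act).sum(axis=0), 0.0)
    if cam.max() <= 0:
        return np.full(image.shape[-2:], 0.5)
    cam /= cam.max()
    return np.clip(
        _sk_resize(cam, x.shape[-2:], order=1, preserve_range=True, anti_aliasing=False), 0.0, 1.0
    )
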