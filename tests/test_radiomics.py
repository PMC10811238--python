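"""Kernel-mean features, selection oracles, and the common/adaptive taxonomy."""

import itertools

import numpy as np
import pytest

from fedrad.model import ModelConfig, build_local_model, count_conv_kernels, small_config
from fedrad.radiomics import (
    FeatureMatrix,
    class_attention_map,
    classify_common_adaptive,
    cross_centre_correlation,
    exact_mwu_p,
    extract_features,
    feature_euclidean_distance,
    mann_whitney_filter,
    mrmr_select,
    select_features,
)


class TestExtractFeatures:
    @pytest.mark.parametrize("seed", range(4))
    def test_column_count_equals_kernel_count(self, seed, rng):
        r = np.random.default_rng(seed)
        cfg = ModelConfig(
            stage_depths=(int(r.integers(1, 3)),),
            stage_widths=(int(r.integers(2, 8)),),
            cbam_enabled=bool(r.integers(0, 2)),
            cbam_reduction=2,
            spatial_kernel=3,
            feature_head_channels=int(r.integers(1, 6)),
            input_size=16,
        )
        model = build_local_model(cfg, seed=0)
        fm = extract_features(model, rng.normal(size=(3, 1, 16, 16)))
        assert fm.values.shape == (3, count_conv_kernels(cfg))

    def test_single_conv_matches_hand_computed_mean(self):
        """A constant input through a known kernel gives a hand-computable mean."""
        cfg = ModelConfig(stage_depths=(1,), stage_widths=(2,), cbam_enabled=False,
                          feature_head_channels=1, input_size=16)
        model = build_local_model(cfg, seed=0)
        # overwrite the stem with a known kernel: all ones, bias 0
        model.stem.params["weight"][...] = 1.0
        model.stem.params["bias"][...] = 0.0
        x = np.ones((1, 1, 16, 16))
        fm = extract_features(model, x)
        # interior pixels see 9 ones; border effects from zero padding:
        # total activation = sum over pixels of (#neighbours in bounds)
        total = sum(
            sum(1 for di in (-1, 0, 1) for dj in (-1, 0, 1)
                if 0 <= i + di < 16 and 0 <= j + dj < 16)
            for i in range(16) for j in range(16)
        )
        expected = total / (16 * 16)
        assert abs(fm.values[0, 0] - expected) < 1e-12

    def test_duplicate_inputs_duplicate_rows(self, small_model, rng):
        x = rng.normal(size=(1, 1, 32, 32))
        fm = extract_features(small_model, np.concatenate([x, x]))
        assert np.array_equal(fm.values[0], fm.values[1])


def _enumeration_oracle(x, y):
    """Independent tie-aware exact two-sided MWU p via direct pair counting."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(group):
        rest = [v for i, v in enumerate(pooled) if i not in group]
        vals = [pooled[i] for i in group]
        u = 0.0
        for a in vals:
            for b in rest:
                u += 1.0 if a > b else (0.5 if a == b else 0.0)
        return u

    mid = n1 * (len(pooled) - n1) / 2
    obs = u_stat(range(n1))
    hits = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_stat(combo) - mid) >= abs(obs - mid) - 1e-12:
            hits += 1
    return obs, hits / total


class TestMannWhitney:
    def test_worked_example(self):
        u, p = exact_mwu_p(np.array([1.0, 2.0]), np.array([3.0, 4.0]))
        assert u == 0.0
        assert abs(p - 1 / 3) < 1e-12

    def test_identical_distributions_p_one(self):
        _, p = exact_mwu_p(np.array([2.0, 2.0, 2.0]), np.array([2.0, 2.0]))
        assert p == 1.0

    @pytest.mark.parametrize("n1,n2", [(2, 2), (2, 3), (3, 3), (4, 3), (5, 5), (4, 5)])
    def test_exact_path_matches_enumeration_oracle(self, n1, n2):
        r = np.random.default_rng(n1 * 10 + n2)
        for trial in range(5):
            x = np.round(r.normal(size=n1), 1)
            y = np.round(r.normal(size=n2), 1)  # rounding induces ties
            u_impl, p_impl = exact_mwu_p(x, y)
            u_orc, p_orc = _enumeration_oracle(x, y)
            assert abs(u_impl - u_orc) < 1e-9
            assert abs(p_impl - p_orc) < 1e-12

    def test_feature_equal_to_label_minimal_p(self):
        y = np.array([1, 1, 1, 0, 0])
        f = y.astype(float).reshape(-1, 1)
        res = mann_whitney_filter(f, y, alpha=0.2)
        # with tied values only the perfectly separating assignment reaches
        # the observed deviation: p = 1 / C(5,3) = 0.1 (enumeration oracle)
        _, p_oracle = _enumeration_oracle(f[y == 1, 0], f[y == 0, 0])
        assert abs(res.p_values[0] - p_oracle) < 1e-12
        assert abs(res.p_values[0] - 0.1) < 1e-12

    def test_filter_keeps_only_significant(self, rng):
        n = 40
        y = np.repeat([0, 1], n // 2)
        signal = y + 0.1 * rng.normal(size=n)
        noise = rng.normal(size=n)
        res = mann_whitney_filter(np.column_stack([signal, noise]), y, alpha=0.01)
        assert res.kept_ids == ["f0"]

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            mann_whitney_filter(rng.normal(size=(6, 2)), np.ones(6, dtype=int))


def _mi_oracle(a, b):
    """Plain histogram mutual information, written independently."""
    a, b = np.asarray(a), np.asarray(b)
    out = 0.0
    n = len(a)
    for va in np.unique(a):
        for vb in np.unique(b):
            pab = np.mean((a == va) & (b == vb))
            if pab > 0:
                out += pab * np.log(pab / (np.mean(a == va) * np.mean(b == vb)))
    return out


def _greedy_oracle(binned, y, k):
    """Exhaustive greedy MID selection evaluated term by term."""
    m = binned.shape[1]
    selected = []
    while len(selected) < k:
        best, best_score = None, -np.inf
        for j in range(m):
            if j in selected:
                continue
            rel = _mi_oracle(binned[:, j], y)
            red = np.mean([_mi_oracle(binned[:, j], binned[:, s]) for s in selected]) if selected else 0.0
            score = rel - red
            if score > best_score + 1e-12:
                best, best_score = j, score
        selected.append(best)
    return selected


class TestMrmr:
    def _binned(self, values, bins=4):
        from fedrad.radiomics import _quantile_bin

        return np.stack([_quantile_bin(values[:, j], bins) for j in range(values.shape[1])], axis=1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_greedy_oracle(self, seed):
        r = np.random.default_rng(seed)
        n, m, k = 40, 6, 3
        y = r.integers(0, 2, size=n)
        x = r.normal(size=(n, m))
        x[:, 0] += y  # give one feature real relevance
        res = mrmr_select(x, y, k=k)
        picked = [int(i[1:]) for i in res.kept_ids]
        assert picked == _greedy_oracle(self._binned(x), y, k)

    def test_label_copy_selected_first(self, rng):
        n = 32
        y = rng.integers(0, 2, size=n)
        x = np.column_stack([rng.normal(size=n), y.astype(float), rng.normal(size=n)])
        res = mrmr_select(x, y, k=2)
        assert res.kept_ids[0] == "f1"

    def test_redundant_copy_penalized(self, rng):
        n = 60
        y = rng.integers(0, 2, size=n)
        top = y + 0.05 * rng.normal(size=n)
        other = 0.7 * y + rng.normal(size=n)  # informative but weaker
        x = np.column_stack([top, top.copy(), other])
        res = mrmr_select(x, y, k=2)
        assert set(res.kept_ids) == {"f0", "f2"}

    def test_k_exceeding_candidates_keeps_all(self, rng):
        x = rng.normal(size=(20, 3))
        y = rng.integers(0, 2, size=20)
        res = mrmr_select(x, y, k=10)
        assert len(res.kept_ids) == 3

    def test_pipeline_retains_exactly_min_k_survivors(self, rng):
        n, m = 60, 30
        y = np.repeat([0, 1], n // 2)
        x = rng.normal(size=(n, m)) + 0.8 * y[:, None]  # all features informative
        fm = FeatureMatrix(values=x, feature_ids=[f"f{i}" for i in range(m)], labels=y)
        res = select_features(fm, y, alpha=0.05, k=10)
        assert len(res.kept_ids) == 10


def _planted_sets(rng, n=120, m=30, n_common=5, n_adaptive=5, noise=0.35):
    """Four centres sharing 5 common factors; 5 centre-specific features each."""
    shared = rng.normal(size=(n, n_common))
    sets, truth = [], {}
    for cid in "ABCD":
        own = rng.normal(size=(n, 1))
        cols = np.empty((n, m))
        cols[:, :n_common] = shared + noise * rng.normal(size=(n, n_common))
        cols[:, n_common:n_common + n_adaptive] = own + noise * rng.normal(size=(n, n_adaptive))
        cols[:, n_common + n_adaptive:] = rng.normal(size=(n, m - n_common - n_adaptive))
        ids = [f"{cid}{j}" for j in range(m)]
        sets.append(FeatureMatrix(values=cols, feature_ids=ids, centre_id=cid))
        truth[cid] = (set(ids[:n_common]), set(ids[n_common:n_common + n_adaptive]))
    return sets, truth


class TestTaxonomy:
    def test_pearson_identities(self, rng):
        x = rng.normal(size=(20, 1))
        fm1 = FeatureMatrix(values=np.hstack([x, -x]), feature_ids=["a", "b"], centre_id="A")
        fm2 = FeatureMatrix(values=x.copy(), feature_ids=["c"], centre_id="B")
        within, between = cross_centre_correlation([fm1, fm2])
        assert abs(within["A"][0, 0] - 1.0) < 1e-12
        assert abs(within["A"][0, 1] + 1.0) < 1e-12
        assert abs(between[("A", "B")][0, 0] - 1.0) < 1e-12

    def test_hand_computed_pearson(self):
        a = FeatureMatrix(values=np.array([[1.0], [2.0], [3.0]]), feature_ids=["x"], centre_id="A")
        b = FeatureMatrix(values=np.array([[1.0], [2.0], [4.0]]), feature_ids=["y"], centre_id="B")
        _, between = cross_centre_correlation([a, b])
        assert abs(between[("A", "B")][0, 0] - 0.98198) < 1e-5

    def test_zero_variance_column_flagged_zero(self, rng):
        a = FeatureMatrix(values=np.ones((10, 1)), feature_ids=["x"], centre_id="A")
        b = FeatureMatrix(values=rng.normal(size=(10, 1)), feature_ids=["y"], centre_id="B")
        _, between = cross_centre_correlation([a, b])
        assert between[("A", "B")][0, 0] == 0.0

    def test_default_counts(self, rng):
        sets, _ = _planted_sets(rng)
        tax = classify_common_adaptive(sets)
        for cid in "ABCD":
            assert len(tax.common_ids[cid]) == 5
            assert len(tax.adaptive_ids[cid]) == 5
            assert not set(tax.common_ids[cid]) & set(tax.adaptive_ids[cid])

    def test_planted_structure_recovered(self, rng):
        sets, truth = _planted_sets(rng)
        tax = classify_common_adaptive(sets)
        hits = total = 0
        for cid in "ABCD":
            true_c, true_a = truth[cid]
            hits += len(set(tax.common_ids[cid]) & true_c)
            hits += len(set(tax.adaptive_ids[cid]) & true_a)
            total += 10
        assert hits / total >= 0.9

    def test_common_features_closer_than_adaptive(self, rng):
        sets, _ = _planted_sets(rng)
        tax = classify_common_adaptive(sets)
        dist = feature_euclidean_distance(tax, sets)
        assert dist["common_mean_distance"] < dist["adaptive_mean_distance"]

    def test_identical_columns_have_zero_distance(self, rng):
        from fedrad.radiomics import FeatureTaxonomy

        col = rng.normal(size=(12, 1))
        a = FeatureMatrix(values=col.copy(), feature_ids=["x"], centre_id="A")
        b = FeatureMatrix(values=col.copy(), feature_ids=["y"], centre_id="B")
        tax = FeatureTaxonomy(common_ids={"A": ["x"], "B": ["y"]}, adaptive_ids={})
        d = feature_euclidean_distance(tax, [a, b])
        assert d["common_mean_distance"] < 1e-12

    def test_distance_is_norm_of_standardized_difference(self, rng):
        from fedrad.radiomics import FeatureTaxonomy

        u = rng.normal(size=12)
        v = rng.normal(size=12)
        a = FeatureMatrix(values=u[:, None], feature_ids=["x"], centre_id="A")
        b = FeatureMatrix(values=v[:, None], feature_ids=["y"], centre_id="B")
        tax = FeatureTaxonomy(common_ids={"A": ["x"], "B": ["y"]}, adaptive_ids={})
        d = feature_euclidean_distance(tax, [a, b])
        zu = (u - u.mean()) / u.std()
        zv = (v - v.mean()) / v.std()
        assert abs(d["common_mean_distance"] - np.linalg.norm(zu - zv)) < 1e-12

    def test_requesting_too_many_features_rejected(self, rng):
        sets = [
            FeatureMatrix(values=rng.normal(size=(20, 8)),
                          feature_ids=[f"{cid}{j}" for j in range(8)], centre_id=cid)
            for cid in "ABCD"
        ]
        with pytest.raises(ValueError):
            classify_common_adaptive(sets, n_common=5, n_adaptive=5)


class TestClassAttention:
    def test_contract_shape_and_range(self, small_model, tiny_cohorts):
        from fedrad.model import prepare_inputs

        train, _ = tiny_cohorts
        x, _ = prepare_inputs(train, 32)
        cam = class_attention_map(small_model, x[0, 0])
        assert cam.shape == (32, 32)
        assert cam.min() >= 0 and cam.max() <= 1

    def test_degenerate_head_gives_uniform_map(self, tiny_cohorts):
        from fedrad.model import prepare_inputs

        model = build_local_model(small_config(), seed=0)
        for mod in (model.head, model.fc):
            for p in mod.params.values():
                p[...] = 0.0
        train, _ = tiny_cohorts
        x, _ = prepare_inputs(train, 32)
        cam = class_attention_map(model, x[0, 0])
        assert np.allclose(cam, 0.5)
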