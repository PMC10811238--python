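"""Robust (personalized) federated aggregation driven by a graph network.

The aggregation scheme replaces FedAvg's single global average with one
personalized parameter set per client:

1. Each client trains locally and shares its flattened parameters.
2. A K x K *relationship matrix* scores how much client i's model "prefers"
   client j's data: entry (i, j) = exp(-mean focal loss of model i on centre
   j's perturbed representative set).  When no representative data exists
   (the GAN-free ablation), pairwise Euclidean parameter distances are used
   instead, converted to similarities with a median-scaled kernel.
3. A small graph convolutional network embeds the clients, and the row-wise
   softmax of the embedding inner products yields a row-stochastic
   *adjacency matrix*.
4. Client i's robust model is the convex combination
   ``theta_hat_i = sum_j A[i, j] * theta_j``.

With a single client the adjacency degenerates to [[1.0]] and the scheme
reduces to pure local training; with a uniform adjacency it reduces to a
plain average.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .cohort import Cohort
from .gan import GanConfig, RepresentativeSet, generate_representative, train_wgan
from .model import (
    LocalModel,
    ModelConfig,
    TrainConfig,
    build_local_model,
    predict_proba,
    prepare_inputs,
    train_local,
)
from .nn import ParameterVector, focal_loss, focal_loss_grad, pack_parameters, unpack_parameters

__all__ = [
    "RelationshipMatrix",
    "AdjacencyMatrix",
    "FederationConfig",
    "relationship_matrix",
    "parameter_distance_matrix",
    "distance_to_similarity",
    "gcn_adjacency",
    "personalize",
    "fedavg",
    "run_federation",
    "FederationResult",
]


@dataclass(frozen=True)
class RelationshipMatrix:
    """Entry (i, j): preference score of client i's model for centre j's data."""

    values: np.ndarray
    mode: str  # "gan_preference" | "parameter_distance"

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] < 1:
            raise ValueError("relationship matrix must be square, K >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("relationship matrix entries must be finite")
        if self.mode == "parameter_distance":
            if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
                raise ValueError("distance mode requires a symmetric, zero-diagonal matrix")

    @property
    def K(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AdjacencyMatrix:
    """Row-stochastic K x K mixing weights."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if np.any(v < 0) or not np.allclose(v.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("adjacency rows must be non-negative and sum to 1")

    @property
    def K(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FederationConfig:
    n_rounds: int = 3
    local_epochs: int = 3
    cbam: bool = True
    fed: bool = True
    gcn: bool = True
    gan: bool = True
    gcn_layers: int = 2
    gcn_hidden: int = 16
    gcn_train_steps: int = 300
    gcn_lr: float = 0.2
    n_representative: int = 8  # per class, per centre
    perturb_sigma: float = 0.1  # 0.05 of the [-1, 1] dynamic range (width 2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gcn and not self.fed:
            raise ValueError("the GCN component requires the federation component")
        if self.gan and not self.gcn:
            raise ValueError("the GAN component relies on the GCN component")


# ---------------------------------------------------------------------------
# Relationship matrices


def _rep_to_input(images: np.ndarray, input_size: int) -> np.ndarray:
    """Representative images ([-1,1]) z-scored per patch into model inputs."""
    from .cohort import normalize_patch

    return np.stack([normalize_patch(im, input_size) for im in images])[:, None]


def relationship_matrix(
    models: list[LocalModel],
    representative_sets: list[RepresentativeSet],
    alpha: float = 0.25,
    gamma: float = 2.0,
) -> RelationshipMatrix:
    """Preference of each model for each centre's representative data.

    Entry (i, j) = exp(-mean focal loss of model i on set j): bounded in
    (0, 1], monotone in preference.
    """
    if len(models) != len(representative_sets):
        raise ValueError("one representative set per model required")
    if len({m.config for m in models}) != 1:
        raise ValueError("all models must share a ModelConfig")
    for rs in representative_sets:
        if rs.class_labels is None or len(rs.class_labels) != len(rs.images):
            raise ValueError("representative sets must be labeled")
    K = len(models)
    values = np.empty((K, K))
    inputs = [
        (_rep_to_input(rs.images, models[0].config.input_size), rs.class_labels)
        for rs in representative_sets
    ]
    for i, model in enumerate(models):
        for j, (x, y) in enumerate(inputs):
            p = predict_proba(model, x)
            values[i, j] = np.exp(-focal_loss(p, y, alpha, gamma))
    return RelationshipMatrix(values=values, mode="gan_preference")


def parameter_distance_matrix(params: list[ParameterVector]) -> RelationshipMatrix:
    """Pairwise Euclidean distances between flattened parameter vectors."""
    layout = params[0].layout
    if any(p.layout != layout for p in params):
        raise ValueError("parameter layouts differ across clients")
    mat = np.stack([p.values for p in params])
    sq = np.sum(mat**2, axis=1)
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * mat @ mat.T, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return RelationshipMatrix(values=d, mode="parameter_distance")


def distance_to_similarity(rel: RelationshipMatrix) -> np.ndarray:
    """exp(-d / median(offdiag d)) — median scaling avoids a free bandwidth."""
    d = rel.values
    off = d[~np.eye(d.shape[0], dtype=bool)]
    med = np.median(off) if off.size and np.median(off) > 0 else 1.0
    return np.exp(-d / med)


# ---------------------------------------------------------------------------
# GCN adjacency


def _node_features(sim: np.ndarray) -> np.ndarray:
    """Permutation-invariant per-node features: own self-similarity followed
    by the sorted similarities to the other clients.  Sorting decouples the
    feature axis from client ordering, making the adjacency construction
    exactly equivariant under client permutation."""
    K = sim.shape[0]
    feats = np.empty_like(sim)
    for i in range(K):
        off = np.delete(sim[i], i)
        feats[i] = np.concatenate([[sim[i, i]], np.sort(off)[::-1]])
    return feats


def _normalized_propagator(sim: np.ndarray) -> np.ndarray:
    a = sim + np.eye(sim.shape[0])
    dinv = 1.0 / np.sqrt(a.sum(axis=1))
    return a * dinv[:, None] * dinv[None, :]


def _row_softmax(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class _GCN:
    """Tiny GCN: `layers` rounds of H <- ReLU(N H W), adjacency from the
    row-softmaxed inner products of the final embeddings."""

    def __init__(self, in_dim: int, hidden: int, layers: int, rng: np.random.Generator) -> None:
        self.weights = []
        dim = in_dim
        for _ in range(layers):
            self.weights.append(rng.normal(0.0, np.sqrt(2.0 / dim), size=(dim, hidden)))
            dim = hidden

    def forward(self, prop: np.ndarray, feats: np.ndarray):
        hs = [feats]
        h = feats
        for w in self.weights:
            h = np.maximum(prop @ h @ w, 0.0)
            hs.append(h)
        scores = h @ h.T
        adj = _row_softmax(scores)
        return adj, scores, hs

    def backward(self, prop: np.ndarray, hs: list[np.ndarray], adj: np.ndarray, dJ_dA: np.ndarray):
        # through row softmax: ds_ij = A_ij (dA_ij - sum_k A_ik dA_ik)
        row_dot = (adj * dJ_dA).sum(axis=1, keepdims=True)
        ds = adj * (dJ_dA - row_dot)
        z = hs[-1]
        dz = (ds + ds.T) @ z
        grads = [None] * len(self.weights)
        dh = dz
        for li in reversed(range(len(self.weights))):
            w = self.weights[li]
            pre = prop @ hs[li] @ w
            dpre = dh * (pre > 0)
            grads[li] = (prop @ hs[li]).T @ dpre
            dh = prop.T @ dpre @ w.T
        return grads


def gcn_adjacency(
    relationship: RelationshipMatrix,
    config: FederationConfig | None = None,
    seed: int | None = None,
    loss_alignment: np.ndarray | None = None,
) -> AdjacencyMatrix:
    """Derive a row-stochastic adjacency from the relationship matrix.

    ``loss_alignment`` (optional, K x K) is the matrix M[i, j] = g_i . theta_j
    used to train the GCN weights: gradient steps on the linearised
    personalized-loss objective J = sum_ij A[i, j] * M[i, j] pull each row of
    the adjacency toward clients whose parameters reduce client i's loss on
    its representative data.  Without it the seeded GCN is applied as-is.
    """
    cfg = config or FederationConfig()
    if not np.all(np.isfinite(relationship.values)):
        raise ValueError("relationship matrix contains non-finite entries")
    sim = (
        distance_to_similarity(relationship)
        if relationship.mode == "parameter_distance"
        else relationship.values
    )
    K = sim.shape[0]
    if K == 1:
        return AdjacencyMatrix(values=np.array([[1.0]]))
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    gcn = _GCN(K, cfg.gcn_hidden, cfg.gcn_layers, rng)
    feats = _node_features(sim)
    prop = _normalized_propagator(sim)
    if loss_alignment is not None:
        # only relative preferences within a row matter: centre and scale each
        # row so the gradient signal is comparable across clients
        m = loss_alignment - loss_alignment.mean(axis=1, keepdims=True)
        m /= m.std(axis=1, keepdims=True) + 1e-12
        for _ in range(cfg.gcn_train_steps):
            adj, _, hs = gcn.forward(prop, feats)
            grads = gcn.backward(prop, hs, adj, m)
            for w, g in zip(gcn.weights, grads):
                w -= cfg.gcn_lr * g
    adj, _, _ = gcn.forward(prop, feats)
    return AdjacencyMatrix(values=adj)


# ---------------------------------------------------------------------------
# Aggregation


def personalize(params: list[ParameterVector], adjacency: AdjacencyMatrix) -> list[ParameterVector]:
    """Robust models: convex combinations theta_hat_i = sum_j A[i,j] theta_j."""
    layout = params[0].layout
    if any(p.layout != layout for p in params):
        raise ValueError("parameter layouts differ across clients")
    a = adjacency.values
    if a.shape[0] != len(params):
        raise ValueError("adjacency size does not match client count")
    mat = np.stack([p.values for p in params])
    mixed = a @ mat
    return [ParameterVector(values=mixed[i].copy(), layout=layout) for i in range(len(params))]


def fedavg(params: list[ParameterVector], sample_sizes: list[int]) -> ParameterVector:
    """Sample-size-weighted average of client parameters (FedAvg)."""
    if len(params) != len(sample_sizes):
        raise ValueError("one sample size per client required")
    if any(s <= 0 for s in sample_sizes):
        raise ValueError("sample sizes must be positive")
    layout = params[0].layout
    if any(p.layout != layout for p in params):
        raise ValueError("parameter layouts differ across clients")
    w = np.asarray(sample_sizes, dtype=float)
    w /= w.sum()
    mat = np.stack([p.values for p in params])
    return ParameterVector(values=w @ mat, layout=layout)


# ---------------------------------------------------------------------------
# Full federation loop


@dataclass
class FederationResult:
    models: list[LocalModel]
    params: list[ParameterVector]
    logs: list[dict]
    representative_sets: list[RepresentativeSet] | None = None

    def write_logs(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for entry in self.logs:
                fh.write(json.dumps(entry) + "\n")


def _loss_gradient(model: LocalModel, x: np.ndarray, y: np.ndarray, tc: TrainConfig) -> np.ndarray:
    """Gradient of the mean focal loss at the model's current parameters."""
    from .model import _softmax_pos

    logits = model.forward(x)
    p = _softmax_pos(logits)
    dp = focal_loss_grad(p, y, tc.focal_alpha, tc.focal_gamma)
    dz = np.zeros_like(logits)
    dpdz = p * (1.0 - p)
    dz[:, 1] = dp * dpdz
    dz[:, 0] = -dp * dpdz
    model.zero_grad()
    model.backward(dz)
    return pack_parameters_grads(model)


def pack_parameters_grads(model: LocalModel) -> np.ndarray:
    chunks = []
    for _, module in model.named_modules():
        for name in module.params:
            chunks.append(module.grads[name].ravel())
    return np.concatenate(chunks)


def run_federation(
    cohorts: list[Cohort],
    fed_config: FederationConfig | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    gan_config: GanConfig | None = None,
) -> FederationResult:
    """Run the full multi-round federation over per-centre training cohorts.

    Per round: local training; then (if federating) build the relationship
    matrix — from WGAN representative data when the GAN component is on,
    from parameter distances otherwise — derive the GCN adjacency and
    personalize, or fall back to a FedAvg broadcast when the GCN component
    is off.  Returns the final per-client models and JSON-able round logs.
    """
    from .model import small_config

    fcfg = fed_config or FederationConfig()
    mcfg = model_config or small_config(cbam=fcfg.cbam)
    if mcfg.cbam_enabled != fcfg.cbam:
        mcfg = ModelConfig(**{**mcfg.__dict__, "cbam_enabled": fcfg.cbam})
    tcfg = train_config or TrainConfig()
    # Desk-scale default: representative patches are synthesized at 16x16 and
    # resized into model inputs downstream, which keeps per-round GAN cost low.
    gcfg = gan_config or GanConfig(
        image_size=16, generator_steps=60, batch_size=8, seed=fcfg.seed
    )

    K = len(cohorts)
    models = [build_local_model(mcfg, seed=fcfg.seed) for _ in range(K)]
    data = [prepare_inputs(c, mcfg.input_size) for c in cohorts]
    sizes = [len(c) for c in cohorts]
    logs: list[dict] = []
    rep_sets: list[RepresentativeSet] | None = None
    generators: list[dict[int, object]] | None = None

    for rnd in range(fcfg.n_rounds):
        params = []
        losses = []
        for i, model in enumerate(models):
            tc = TrainConfig(
                epochs=fcfg.local_epochs,
                batch_size=tcfg.batch_size,
                learning_rate=tcfg.learning_rate,
                momentum=tcfg.momentum,
                optimizer=tcfg.optimizer,
                focal_alpha=tcfg.focal_alpha,
                focal_gamma=tcfg.focal_gamma,
                seed=int(np.random.default_rng([fcfg.seed, rnd, i]).integers(2**31)),
            )
            pv, trace = train_local(model, data[i], tc)
            params.append(pv)
            losses.append(trace[-1])

        entry: dict = {"round": rnd, "client_losses": losses}
        if fcfg.fed:
            if fcfg.gan:
                if generators is None:
                    generators = _train_centre_gans(cohorts, gcfg, fcfg)
                rep_sets = [
                    _perturbed_set(generators[i], cohorts[i].spec.centre_id, fcfg, gcfg, rnd, i)
                    for i in range(K)
                ]
                rel = relationship_matrix(models, rep_sets, tcfg.focal_alpha, tcfg.focal_gamma)
            else:
                rel = parameter_distance_matrix(params)
            entry["relationship"] = rel.values.tolist()

            if fcfg.gcn:
                alignment = _alignment_matrix(models, params, rep_sets, data, tcfg)
                adj = gcn_adjacency(rel, fcfg, seed=fcfg.seed, loss_alignment=alignment)
                new_params = personalize(params, adj)
                entry["adjacency"] = adj.values.tolist()
            else:
                avg = fedavg(params, sizes)
                new_params = [avg.copy() for _ in range(K)]
            for model, pv in zip(models, new_params):
                unpack_parameters(model, pv)
            params = new_params
        logs.append(entry)

    return FederationResult(models=models, params=params, logs=logs, representative_sets=rep_sets)


def _train_centre_gans(cohorts, gcfg: GanConfig, fcfg: FederationConfig):
    """One WGAN per (centre, class), trained once on [-1, 1]-scaled patches."""
    from .cohort import crop_roi
    from .model import prepare_inputs  # noqa: F401  (kept for symmetry)

    generators = []
    for i, cohort in enumerate(cohorts):
        per_class: dict[int, object] = {}
        imgs = np.stack(
            [
                _to_unit_range(crop_roi(p.image, p.lesion_mask, 2), gcfg.image_size)
                for p in cohort.patients
            ]
        )
        y = cohort.labels
        for label in (0, 1):
            sub = imgs[y == label]
            cfg_i = GanConfig(**{**gcfg.__dict__, "seed": int(np.random.default_rng([fcfg.seed, 7, i, label]).integers(2**31))})
            gen, _, _ = train_wgan(sub, cfg_i)
            per_class[label] = gen
        generators.append(per_class)
    return generators


def _to_unit_range(patch: np.ndarray, size: int) -> np.ndarray:
    from skimage.transform import resize

    p = resize(patch.astype(float), (size, size), order=1, preserve_range=True, anti_aliasing=False)
    lo, hi = p.min(), p.max()
    if hi - lo < 1e-12:
        return np.zeros_like(p)
    return 2.0 * (p - lo) / (hi - lo) - 1.0


def _perturbed_set(per_class_gens, centre_id, fcfg, gcfg, rnd, i) -> RepresentativeSet:
    from .gan import generate_representative, perturb_gaussian

    seed = int(np.random.default_rng([fcfg.seed, 11, rnd, i]).integers(2**31))
    rep = generate_representative(
        per_class_gens, fcfg.n_representative, seed, centre_id=centre_id, latent_dim=gcfg.latent_dim
    )
    return perturb_gaussian(rep, fcfg.perturb_sigma, seed + 1)


def _alignment_matrix(models, params, rep_sets, data, tcfg) -> np.ndarray:
    """M[i, j] = g_i . theta_j, with g_i the focal-loss gradient of client i's
    model on its own representative data (or its local data without GAN)."""
    K = len(models)
    grads = []
    for i, model in enumerate(models):
        if rep_sets is not None:
            x = _rep_to_input(rep_sets[i].images, model.config.input_size)
            y = rep_sets[i].class_labels
        else:
            x, y = data[i]
        grads.append(_loss_gradient(model, x, y, tcfg))
    theta = np.stack([p.values for p in params])
    g = np.stack(grads)
    return g @ theta.T
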