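"""Sparse Bayesian extreme learning machine (SBELM).

A frozen random hidden layer (uniform weights, sigmoid activation) maps
inputs to hidden features; a Bayesian logistic output layer with an
automatic-relevance-determination (ARD) prior — one precision alpha_i per
output weight — is fitted by alternating a Laplace approximation of the
posterior mode (iteratively reweighted least squares) with the evidence
update ``alpha_i <- gamma_i / mu_i**2``, ``gamma_i = 1 - alpha_i * Sigma_ii``.
Weights whose precision diverges are pruned to exactly zero, giving a sparse
classifier; predictions optionally moderate the sigmoid with the posterior
variance (probit approximation) for calibrated probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SBELMModel", "init_hidden", "hidden_map", "fit", "predict_proba",
           "SBELM", "save_model", "load_model"]

_PRUNE_THRESHOLD = 1e9


@dataclass
class SBELMModel:
    hidden_weights: np.ndarray  # (input_dim, n_hidden)
    hidden_biases: np.ndarray  # (n_hidden,)
    weight_mean: np.ndarray  # (n_hidden + 1,)  output weights + bias (last)
    weight_cov: np.ndarray  # posterior covariance over ACTIVE weights
    alpha: np.ndarray  # (n_hidden + 1,) ARD precisions
    pruned_mask: np.ndarray  # True where the weight has been pruned to 0
    converged: bool
    n_iter: int
    moderated: bool = True

    def __post_init__(self) -> None:
        if np.any(self.alpha <= 0):
            raise ValueError("ARD precisions must be positive")
        if np.any(self.weight_mean[self.pruned_mask] != 0):
            raise ValueError("pruned weights must have mean exactly 0")


def save_model(model: SBELMModel, path) -> None:
    """Serialize a fitted model to JSON (arrays as nested lists)."""
    import json
    from pathlib import Path

    payload = {
        "hidden_weights": model.hidden_weights.tolist(),
        "hidden_biases": model.hidden_biases.tolist(),
        "weight_mean": model.weight_mean.tolist(),
        "weight_cov": model.weight_cov.tolist(),
        "alpha": model.alpha.tolist(),
        "pruned_mask": model.pruned_mask.tolist(),
        "converged": model.converged,
        "n_iter": model.n_iter,
        "moderated": model.moderated,
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path) -> SBELMModel:
    import json
    from pathlib import Path

    d = json.loads(Path(path).read_text())
    return SBELMModel(
        hidden_weights=np.array(d["hidden_weights"]),
        hidden_biases=np.array(d["hidden_biases"]),
        weight_mean=np.array(d["weight_mean"]),
        weight_cov=np.array(d["weight_cov"]),
        alpha=np.array(d["alpha"]),
        pruned_mask=np.array(d["pruned_mask"], dtype=bool),
        converged=bool(d["converged"]),
        n_iter=int(d["n_iter"]),
        moderated=bool(d["moderated"]),
    )


def init_hidden(n_hidden: int, input_dim: int, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Random frozen hidden layer: weights and biases ~ Uniform(-1, 1)."""
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1.0, 1.0, size=(input_dim, n_hidden))
    b = rng.uniform(-1.0, 1.0, size=n_hidden)
    return w, b


def hidden_map(X: np.ndarray, weights: np.ndarray, biases: np.ndarray) -> np.ndarray:
    """Sigmoid hidden activations, with an appended constant bias column."""
    h = 1.0 / (1.0 + np.exp(-np.clip(X @ weights + biases, -60, 60)))
    return np.hstack([h, np.ones((len(h), 1))])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))


def fit(
    H: np.ndarray,
    labels: np.ndarray,
    hidden_weights: np.ndarray | None = None,
    hidden_biases: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-4,
    moderated: bool = True,
) -> SBELMModel:
    """Fit the ARD logistic output layer on a precomputed hidden map ``H``.

    ``H`` must include the bias column (as produced by :func:`hidden_map`).
    Stops when ``max |delta alpha| / alpha < tol`` over active weights or
    after ``max_iter`` outer iterations.  Pruned weights never re-enter.
    """
    y = np.asarray(labels).astype(float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required to fit")
    n, d = H.shape
    alpha = np.full(d, 1e-2)
    active = np.ones(d, dtype=bool)
    mu = np.zeros(d)
    cov_active = np.eye(d)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        idx = np.nonzero(active)[0]
        ha = H[:, idx]
        mu_a = mu[idx]
        # Laplace: Newton/IRLS for the posterior mode of active weights
        for _ in range(50):
            p = _sigmoid(ha @ mu_a)
            g = ha.T @ (p - y) + alpha[idx] * mu_a
            r = np.clip(p * (1 - p), 1e-10, None)
            hess = (ha * r[:, None]).T @ ha + np.diag(alpha[idx])
            try:
                step = np.linalg.solve(hess, g)
            except np.linalg.LinAlgError:
                hess += 1e-8 * np.eye(len(idx))  # ridge jitter for singular Hessian
                step = np.linalg.solve(hess, g)
            mu_a = mu_a - step
            if np.max(np.abs(step)) < 1e-8:
                break
        p = _sigmoid(ha @ mu_a)
        r = np.clip(p * (1 - p), 1e-10, None)
        hess = (ha * r[:, None]).T @ ha + np.diag(alpha[idx])
        try:
            cov_active = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_active = np.linalg.inv(hess + 1e-8 * np.eye(len(idx)))
        sii = np.clip(np.diag(cov_active), 1e-300, None)
        gamma = 1.0 - alpha[idx] * sii
        gamma = np.clip(gamma, 1e-12, None)
        new_alpha = gamma / np.clip(mu_a**2, 1e-300, None)
        rel_change = np.max(np.abs(new_alpha - alpha[idx]) / alpha[idx])
        alpha[idx] = new_alpha
        mu[:] = 0.0
        mu[idx] = mu_a
        # prune diverged weights (they never re-enter)
        prune = new_alpha > _PRUNE_THRESHOLD
        if prune.any():
            active[idx[prune]] = False
            mu[idx[prune]] = 0.0
            if not active.any():
                break
        if rel_change < tol:
            converged = True
            break

    # final posterior covariance over the surviving active set
    idx = np.nonzero(active)[0]
    if idx.size:
        ha = H[:, idx]
        p = _sigmoid(ha @ mu[idx])
        r = np.clip(p * (1 - p), 1e-10, None)
        hess = (ha * r[:, None]).T @ ha + np.diag(alpha[idx])
        try:
            cov_active = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov_active = np.linalg.inv(hess + 1e-8 * np.eye(len(idx)))
    else:
        cov_active = np.zeros((0, 0))

    hw = hidden_weights if hidden_weights is not None else np.empty((0, d - 1))
    hb = hidden_biases if hidden_biases is not None else np.empty(d - 1)
    return SBELMModel(
        hidden_weights=hw,
        hidden_biases=hb,
        weight_mean=mu,
        weight_cov=cov_active,
        alpha=alpha,
        pruned_mask=~active,
        converged=converged,
        n_iter=it,
        moderated=moderated,
    )


def predict_proba(model: SBELMModel, X_or_H: np.ndarray, is_hidden: bool = False) -> np.ndarray:
    """Positive-class probabilities sigma(h . mu), optionally moderated by the
    posterior variance: sigma(m / sqrt(1 + pi s^2 / 8))."""
    if model.weight_mean is None:
        raise ValueError("model is not fitted")
    if is_hidden:
        H = X_or_H
    else:
        if model.hidden_weights.size == 0:
            raise ValueError("model carries no hidden layer; pass the hidden map directly")
        H = hidden_map(X_or_H, model.hidden_weights, model.hidden_biases)
    m = H @ model.weight_mean
    if not model.moderated:
        return _sigmoid(m)
    idx = np.nonzero(~model.pruned_mask)[0]
    if idx.size == 0:
        return _sigmoid(m)
    ha = H[:, idx]
    s2 = np.einsum("ij,jk,ik->i", ha, model.weight_cov, ha)
    return _sigmoid(m / np.sqrt(1.0 + np.pi * np.clip(s2, 0, None) / 8.0))


class SBELM:
    """Convenience wrapper: random hidden layer + ARD output layer.

    Parameters
    ----------
    n_hidden:
        Hidden width; 50 is a reasonable default for ~200 input features.
    """

    def __init__(self, n_hidden: int = 50, seed: int = 0, max_iter: int = 200,
                 tol: float = 1e-4, moderated: bool = True) -> None:
        self.n_hidden = n_hidden
        self.seed = seed
        self.max_iter = max_iter
        self.tol = tol
        self.moderated = moderated
        self.model_: SBELMModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SBELM":
        X = np.asarray(X, dtype=float)
        w, b = init_hidden(self.n_hidden, X.shape[1], self.seed)
        H = hidden_map(X, w, b)
        self.model_ = fit(H, y, hidden_weights=w, hidden_biases=b,
                          max_iter=self.max_iter, tol=self.tol, moderated=self.moderated)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.model_ is None:
            raise ValueError("call fit first")
        return predict_proba(self.model_, np.asarray(X, dtype=float))
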