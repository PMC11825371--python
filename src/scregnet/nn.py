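"""Per-gene neural networks and the consolidated training objective.

One model per target gene: inputs are the TF expression vector concatenated
with the accessibility of candidate REs within 1 Mb of the TSS, two hidden
layers (64, 16) with ReLU, and a scalar expression output. Training is
full-batch Adam. The refinement objective is

    L = l1 * MSE + l2 * ||theta||_1 + l3 * tr(W1' L_norm W1) + l4 * EWC

where L_norm is the normalized Laplacian of the TF-RE binding-affinity graph
(manifold regularization: motif-matched TF-RE pairs share first-layer
embeddings) and EWC is the Fisher-weighted squared distance of the
first-layer weights from the bulk pre-trained ones (elastic weight
consolidation). The Fisher information is the mean squared per-sample MSE
gradient, estimated on the bulk data.

Everything here operates on prepared numeric arrays; scaling/log transforms
live in :mod:`scregnet.pipeline`.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneModelSpec",
    "ModelParams",
    "LossWeights",
    "TrainResult",
    "build_adjacency",
    "normalized_laplacian",
    "laplace_penalty",
    "ewc_penalty",
    "predict",
    "bulk_pretrain",
    "train_single_cell",
    "consolidated_refine",
]


@dataclass(frozen=True)
class GeneModelSpec:
    """Architecture and the fixed feature order (TFs first, then REs)."""

    gene_id: str
    tf_ids: tuple[str, ...]
    re_ids: tuple[str, ...]
    hidden_sizes: tuple[int, int] = (64, 16)
    activation: str = "relu"

    def __post_init__(self):
        if self.activation not in ("relu", "sigmoid"):
            raise ValueError(f"unknown activation {self.activation!r}")

    @property
    def feature_ids(self) -> tuple[str, ...]:
        return tuple(self.tf_ids) + tuple(self.re_ids)

    @property
    def n_features(self) -> int:
        return len(self.tf_ids) + len(self.re_ids)


@dataclass
class ModelParams:
    """Weights/biases; W1 is the (n_features x h1) first-layer matrix."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    W3: np.ndarray
    b3: np.ndarray

    def copy(self) -> "ModelParams":
        return ModelParams(*(getattr(self, f).copy() for f in self._fields()))

    @staticmethod
    def _fields():
        return ("W1", "b1", "W2", "b2", "W3", "b3")

    def arrays(self):
        return [getattr(self, f) for f in self._fields()]

    def l1_norm(self) -> float:
        return float(sum(np.abs(a).sum() for a in self.arrays()))

    def check_finite(self) -> None:
        for f in self._fields():
            if not np.isfinite(getattr(self, f)).all():
                raise FloatingPointError(f"non-finite values in parameter {f}")


@dataclass(frozen=True)
class LossWeights:
    """lambda0: bulk L1; lambda1..4: MSE, L1, Laplace, EWC weights."""

    lambda0: float = 1e-3
    lambda1: float = 1.0
    lambda2: float = 1e-3
    lambda3: float = 0.01
    lambda4: float = 1.0

    def __post_init__(self):
        for name in ("lambda0", "lambda1", "lambda2", "lambda3", "lambda4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class TrainResult:
    params: ModelParams
    history: pd.DataFrame  # epoch + each loss term
    fisher: np.ndarray | None = None


def build_adjacency(B_gene: np.ndarray) -> np.ndarray:
    """Bipartite adjacency over TF and RE nodes; TF-TF and RE-RE blocks are 0."""
    B_gene = np.asarray(B_gene, dtype=float)
    if (B_gene < 0).any():
        raise ValueError("binding affinities must be >= 0")
    n_tf, n_re = B_gene.shape
    n = n_tf + n_re
    adj = np.zeros((n, n))
    adj[:n_tf, n_tf:] = B_gene
    adj[n_tf:, :n_tf] = B_gene.T
    return adj


def normalized_laplacian(adjacency: np.ndarray) -> np.ndarray:
    """L = I - D^{-1/2} A D^{-1/2}; isolated nodes get zero row, column and diagonal.

    Symmetric positive semidefinite with eigenvalues in [0, 2].
    """
    A = np.asarray(adjacency, dtype=float)
    if A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if np.abs(A - A.T).max(initial=0.0) > 1e-10:
        raise ValueError("adjacency must be symmetric")
    if (A < 0).any():
        raise ValueError("adjacency must be nonnegative")
    deg = A.sum(axis=1)
    connected = deg > 0
    # divide by sqrt(d_i * d_j) in one step: exact for integer-degree cases
    denom = np.sqrt(np.outer(deg, deg))
    denom[denom == 0] = 1.0
    L = -A / denom
    L[np.diag_indices_from(L)] = np.where(connected, 1.0, 0.0)
    return L


def laplace_penalty(theta1: np.ndarray, laplacian: np.ndarray) -> float:
    """Manifold regularization tr(theta1' L theta1); >= 0 by PSD of L."""
    theta1 = np.asarray(theta1, dtype=float)
    if theta1.shape[0] != laplacian.shape[0]:
        raise ValueError(
            f"theta1 has {theta1.shape[0]} rows but Laplacian is {laplacian.shape[0]}-dim"
        )
    return float(np.einsum("ik,ij,jk->", theta1, laplacian, theta1))


def ewc_penalty(
    theta_l1: np.ndarray,
    theta_b1: np.ndarray,
    fisher: np.ndarray,
    form: str = "squared",
) -> float:
    """Elastic-weight-consolidation penalty on the first-layer weights.

    Default is the Fisher-weighted mean squared difference between refined
    and pre-trained parameters. ``form="product"`` computes the raw product
    F * theta_l * theta_b instead (compatibility switch; unbounded below and
    not usable as a consolidation penalty).
    """
    theta_l1 = np.asarray(theta_l1, float)
    theta_b1 = np.asarray(theta_b1, float)
    fisher = np.asarray(fisher, float)
    if not (theta_l1.shape == theta_b1.shape == fisher.shape):
        raise ValueError("theta_l1, theta_b1 and fisher must share a shape")
    if (fisher < 0).any():
        raise ValueError("Fisher information must be >= 0")
    scale = 1.0 / theta_l1.size
    if form == "squared":
        return float(scale * (fisher * (theta_l1 - theta_b1) ** 2).sum())
    if form == "product":
        return float(scale * (fisher * theta_l1 * theta_b1).sum())
    raise ValueError(f"unknown EWC form {form!r}")


def _act(z: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return np.maximum(z, 0.0)
    return 1.0 / (1.0 + np.exp(-z))


def _act_grad(z: np.ndarray, a: np.ndarray, kind: str) -> np.ndarray:
    if kind == "relu":
        return (z > 0).astype(float)
    return a * (1.0 - a)


def _forward(params: ModelParams, X: np.ndarray, activation: str):
    z1 = X @ params.W1 + params.b1
    a1 = _act(z1, activation)
    z2 = a1 @ params.W2 + params.b2
    a2 = _act(z2, activation)
    y = a2 @ params.W3[:, 0] + params.b3[0]
    return y, (z1, a1, z2, a2)


def predict(spec: GeneModelSpec, params: ModelParams, X: np.ndarray) -> np.ndarray:
    """Forward pass; ``X`` is (n_samples, n_features) in the spec's feature order."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.n_features:
        raise ValueError(f"expected {spec.n_features} features, got {X.shape[1]}")
    y, _ = _forward(params, X, spec.activation)
    return y


def _backward(params: ModelParams, X: np.ndarray, dy: np.ndarray, cache, activation: str):
    """Gradients of sum_n dy_n * y_n w.r.t. all parameters."""
    z1, a1, z2, a2 = cache
    d2 = dy[:, None] * params.W3[:, 0][None, :] * _act_grad(z2, a2, activation)
    d1 = (d2 @ params.W2.T) * _act_grad(z1, a1, activation)
    return ModelParams(
        W1=X.T @ d1,
        b1=d1.sum(axis=0),
        W2=a1.T @ d2,
        b2=d2.sum(axis=0),
        W3=(a2.T @ dy)[:, None],
        b3=np.array([dy.sum()]),
    )


def init_params(spec: GeneModelSpec, seed: int) -> ModelParams:
    """He-style initialization, deterministic given the seed."""
    rng = np.random.default_rng(seed)
    d, (h1, h2) = spec.n_features, spec.hidden_sizes

    def layer(n_in, n_out):
        return rng.standard_normal((n_in, n_out)) * math.sqrt(2.0 / n_in)

    return ModelParams(
        W1=layer(d, h1),
        b1=np.zeros(h1),
        W2=layer(h1, h2),
        b2=np.zeros(h2),
        W3=layer(h2, 1),
        b3=np.zeros(1),
    )


@dataclass
class _Objective:
    """Total loss = mse_weight*MSE + l1_weight*L1 + laplace + EWC terms."""

    mse_weight: float
    l1_weight: float
    laplace_weight: float = 0.0
    laplacian: np.ndarray | None = None
    ewc_weight: float = 0.0
    theta_b1: np.ndarray | None = None
    fisher: np.ndarray | None = None
    ewc_form: str = "squared"

    def terms(self, params: ModelParams, X, y) -> dict[str, float]:
        pred, _ = _forward(params, X, self.activation)
        out = {"mse": float(np.mean((pred - y) ** 2)), "l1": params.l1_norm()}
        out["laplace"] = (
            laplace_penalty(params.W1, self.laplacian) if self.laplace_weight != 0 else 0.0
        )
        out["ewc"] = (
            ewc_penalty(params.W1, self.theta_b1, self.fisher, self.ewc_form)
            if self.ewc_weight != 0
            else 0.0
        )
        out["total"] = (
            self.mse_weight * out["mse"]
            + self.l1_weight * out["l1"]
            + self.laplace_weight * out["laplace"]
            + self.ewc_weight * out["ewc"]
        )
        return out

    activation: str = "relu"

    def gradient(self, params: ModelParams, X, y) -> tuple[ModelParams, dict[str, float]]:
        n = X.shape[0]
        pred, cache = _forward(params, X, self.activation)
        resid = pred - y
        grads = _backward(params, X, self.mse_weight * 2.0 * resid / n, cache, self.activation)
        if self.l1_weight != 0:
            for f in ModelParams._fields():
                getattr(grads, f)[...] += self.l1_weight * np.sign(getattr(params, f))
        if self.laplace_weight != 0:
            grads.W1 += self.laplace_weight * 2.0 * (self.laplacian @ params.W1)
        if self.ewc_weight != 0:
            scale = self.ewc_weight / params.W1.size
            if self.ewc_form == "squared":
                grads.W1 += scale * 2.0 * self.fisher * (params.W1 - self.theta_b1)
            else:
                grads.W1 += scale * self.fisher * self.theta_b1
        terms = {
            "mse": float(np.mean(resid**2)),
            "l1": params.l1_norm(),
            "laplace": laplace_penalty(params.W1, self.laplacian)
            if self.laplace_weight != 0
            else 0.0,
            "ewc": ewc_penalty(params.W1, self.theta_b1, self.fisher, self.ewc_form)
            if self.ewc_weight != 0
            else 0.0,
        }
        terms["total"] = (
            self.mse_weight * terms["mse"]
            + self.l1_weight * terms["l1"]
            + self.laplace_weight * terms["laplace"]
            + self.ewc_weight * terms["ewc"]
        )
        return grads, terms


def _adam_train(
    spec: GeneModelSpec,
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    objective: _Objective,
    epochs: int,
    lr: float,
    patience: int,
) -> TrainResult:
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m = [np.zeros_like(a) for a in params.arrays()]
    v = [np.zeros_like(a) for a in params.arrays()]
    fields = ModelParams._fields()
    best_total = np.inf
    best_params = params.copy()
    stale = 0
    rows = []
    for epoch in range(1, epochs + 1):
        grads, terms = objective.gradient(params, X, y)
        if not np.isfinite(terms["total"]):
            raise FloatingPointError(
                f"non-finite loss for gene {spec.gene_id} at epoch {epoch}: {terms}"
            )
        for i, f in enumerate(fields):
            g = getattr(grads, f)
            m[i] = beta1 * m[i] + (1 - beta1) * g
            v[i] = beta2 * v[i] + (1 - beta2) * g * g
            mhat = m[i] / (1 - beta1**epoch)
            vhat = v[i] / (1 - beta2**epoch)
            getattr(params, f)[...] -= lr * mhat / (np.sqrt(vhat) + eps)
        rows.append({"epoch": epoch, **terms})
        if terms["total"] < best_total - 1e-12:
            best_total = terms["total"]
            best_params = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= patience:
                break
    best_params.check_finite()
    return TrainResult(params=best_params, history=pd.DataFrame(rows))


def _prep(X, y, spec):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape != (len(y), spec.n_features):
        raise ValueError(
            f"X shape {X.shape} does not match ({len(y)}, {spec.n_features}) for {spec.gene_id}"
        )
    return X, y


def bulk_pretrain(
    spec: GeneModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    weights: LossWeights = LossWeights(),
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    patience: int = 20,
) -> TrainResult:
    """Fit MSE + lambda0*L1 on bulk samples, then estimate the diagonal Fisher.

    Fisher entry F_ij is the mean over samples of the squared gradient of the
    per-sample squared error with respect to the first-layer weight (i, j).
    A zero-residual fit therefore has F = 0.
    """
    X, y = _prep(X, y, spec)
    if len(y) < 2:
        raise ValueError("bulk pre-training needs at least 2 samples")
    params = init_params(spec, seed)
    objective = _Objective(mse_weight=1.0, l1_weight=weights.lambda0, activation=spec.activation)
    result = _adam_train(spec, params, X, y, objective, epochs, lr, patience)
    result.fisher = fisher_information(spec, result.params, X, y)
    return result


def fisher_information(
    spec: GeneModelSpec, params: ModelParams, X: np.ndarray, y: np.ndarray
) -> np.ndarray:
    """Diagonal Fisher of the first layer on (X, y): mean_n (d(r_n^2)/dW1)^2."""
    X, y = _prep(X, y, spec)
    pred, cache = _forward(params, X, spec.activation)
    z1, a1, z2, a2 = cache
    resid = pred - y
    dy = 2.0 * resid  # per-sample gradient of r_n^2 at the output
    d2 = dy[:, None] * params.W3[:, 0][None, :] * _act_grad(z2, a2, spec.activation)
    d1 = (d2 @ params.W2.T) * _act_grad(z1, a1, spec.activation)
    # per-sample W1 gradient is outer(x_n, d1_n); square factorizes
    return (X**2).T @ (d1**2) / len(y)


def train_single_cell(
    spec: GeneModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    weights: LossWeights = LossWeights(),
    init: ModelParams | None = None,
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    patience: int = 20,
) -> TrainResult:
    """Plain single-cell fit (no pre-training terms): lambda1*MSE + lambda2*L1."""
    X, y = _prep(X, y, spec)
    params = init.copy() if init is not None else init_params(spec, seed)
    objective = _Objective(
        mse_weight=weights.lambda1, l1_weight=weights.lambda2, activation=spec.activation
    )
    return _adam_train(spec, params, X, y, objective, epochs, lr, patience)


def consolidated_refine(
    spec: GeneModelSpec,
    theta_b: ModelParams,
    fisher: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    B_gene: np.ndarray,
    weights: LossWeights = LossWeights(),
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    patience: int = 20,
    ewc_form: str = "squared",
) -> TrainResult:
    """Refine the bulk model on single-cell (metacell) data with all four terms.

    Initialized at the pre-trained parameters; with lambda3 = lambda4 = 0 the
    objective (and the trajectory, bit for bit) reduces to the plain
    single-cell fit started at theta_b.
    """
    X, y = _prep(X, y, spec)
    if len(y) < 2:
        raise ValueError("refinement needs at least 2 metacells")
    laplacian = None
    if weights.lambda3 != 0:
        laplacian = normalized_laplacian(build_adjacency(np.asarray(B_gene, float)))
        if laplacian.shape[0] != spec.n_features:
            raise ValueError("binding-affinity graph does not match the feature order")
    objective = _Objective(
        mse_weight=weights.lambda1,
        l1_weight=weights.lambda2,
        laplace_weight=weights.lambda3,
        laplacian=laplacian,
        ewc_weight=weights.lambda4,
        theta_b1=theta_b.W1.copy(),
        fisher=np.asarray(fisher, float),
        ewc_form=ewc_form,
        activation=spec.activation,
    )
    return _adam_train(spec, theta_b.copy(), X, y, objective, epochs, lr, patience)
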