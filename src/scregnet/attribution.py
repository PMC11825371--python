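"""Shapley-value feature attribution for trained per-gene models.

The regulation strength of a TF or RE on its target gene is the mean
absolute Shapley value of the corresponding input feature across samples.
The value function of a coalition S replaces features outside S with a
baseline (per-feature mean of the training metacells by default).

Two routes are provided: a permutation sampler (antithetic pairs; exact
enumeration of all n! permutations once the budget covers them) and an
exact subset-enumeration oracle for <= 12 features used to validate the
sampler.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .nn import GeneModelSpec, ModelParams, predict

__all__ = [
    "GeneAttribution",
    "shapley_attributions",
    "shapley_values",
    "exact_shapley_oracle",
]


@dataclass
class GeneAttribution:
    """Per-gene attribution summary: mean |Shapley| split into TF and RE parts."""

    gene_id: str
    tf_ids: tuple[str, ...]
    re_ids: tuple[str, ...]
    phi: np.ndarray  # n_samples x n_features signed Shapley values
    mean_abs: np.ndarray  # n_features

    @property
    def gamma(self) -> np.ndarray:
        """Trans-regulatory strength: mean |phi| of the TF features."""
        return self.mean_abs[: len(self.tf_ids)]

    @property
    def beta(self) -> np.ndarray:
        """Cis-regulatory strength: mean |phi| of the RE features."""
        return self.mean_abs[len(self.tf_ids) :]

    @property
    def tf_abs(self) -> np.ndarray:
        """Per-sample mean |phi| over TF features (for dominance testing)."""
        return np.abs(self.phi[:, : len(self.tf_ids)]).mean(axis=1)

    @property
    def re_abs(self) -> np.ndarray:
        return np.abs(self.phi[:, len(self.tf_ids) :]).mean(axis=1)


def _sampled_permutations(n_features: int, n_perm: int, rng) -> np.ndarray:
    """Antithetic permutation draws; enumerates all n! once the budget covers them."""
    total = math.factorial(n_features)
    if n_perm >= total:
        return np.array(list(permutations(range(n_features))), dtype=int)
    perms = np.empty((n_perm, n_features), dtype=int)
    for i in range(0, n_perm, 2):
        p = rng.permutation(n_features)
        perms[i] = p
        if i + 1 < n_perm:
            perms[i + 1] = p[::-1]  # antithetic: reversed order
    return perms


def shapley_values(
    spec: GeneModelSpec,
    params: ModelParams,
    samples: np.ndarray,
    baseline: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Signed Shapley values, (n_samples x n_features), by permutation sampling.

    For each sampled feature order, features are switched from baseline to
    their observed value one at a time; the output increments are the
    marginal contributions. Each permutation's contributions sum exactly to
    f(x) - f(baseline), so the efficiency axiom holds for the estimate.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    baseline = np.asarray(baseline, dtype=float).ravel()
    n_samples, d = samples.shape
    if d != spec.n_features or baseline.size != d:
        raise ValueError("samples/baseline do not match the feature order")
    rng = np.random.default_rng(seed)
    perms = _sampled_permutations(d, n_perm, rng)
    phi = np.zeros((n_samples, d))
    for order in perms:
        # batched forward passes over the d+1 coalition prefixes
        X = np.tile(baseline, (n_samples * (d + 1), 1))
        for step, feat in enumerate(order, start=1):
            block = slice(step * n_samples, None)
            X[block, feat] = np.tile(samples[:, feat], d + 1 - step)
        out = predict(spec, params, X).reshape(d + 1, n_samples)
        phi[:, order] += (out[1:] - out[:-1]).T
    return phi / len(perms)


def shapley_attributions(
    spec: GeneModelSpec,
    params: ModelParams,
    samples: np.ndarray,
    baseline: np.ndarray | None = None,
    n_perm: int = 200,
    seed: int = 0,
) -> GeneAttribution:
    """Mean absolute Shapley value per feature across samples.

    The default baseline is the per-feature mean of ``samples``.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if baseline is None:
        baseline = samples.mean(axis=0)
    phi = shapley_values(spec, params, samples, baseline, n_perm=n_perm, seed=seed)
    return GeneAttribution(
        gene_id=spec.gene_id,
        tf_ids=tuple(spec.tf_ids),
        re_ids=tuple(spec.re_ids),
        phi=phi,
        mean_abs=np.abs(phi).mean(axis=0),
    )


def exact_shapley_oracle(model, sample: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Exact Shapley values by 2^n subset enumeration (test oracle, n <= 12).

    ``model`` maps a (k, n_features) array to k outputs. The value of a
    coalition S is f(x with features outside S at baseline).
    """
    sample = np.asarray(sample, dtype=float).ravel()
    baseline = np.asarray(baseline, dtype=float).ravel()
    d = sample.size
    if d > 12:
        raise ValueError("exact enumeration limited to 12 features")
    # value of every subset, indexed by bitmask
    masks = np.arange(2**d)
    X = np.where((masks[:, None] >> np.arange(d)) & 1, sample, baseline)
    values = np.asarray(model(X), dtype=float).ravel()
    fact = [math.factorial(k) for k in range(d + 1)]
    sizes = np.array([bin(m).count("1") for m in masks])
    phi = np.zeros(d)
    for i in range(d):
        without = masks[(masks >> i) & 1 == 0]
        s = sizes[without]
        w = np.array([fact[k] * fact[d - k - 1] / fact[d] for k in s])
        phi[i] = float(np.sum(w * (values[without | (1 << i)] - values[without])))
    return phi
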