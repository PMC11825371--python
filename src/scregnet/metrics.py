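"""Benchmark metrics against a ground-truth network.

The AUPR ratio divides the area under the precision-recall curve by the
positive fraction — the AUPR of a random predictor — so 1 means random and
larger is better. AUC uses the Mann-Whitney formulation with tie
correction; AUPR is step-wise (non-interpolated) with tied scores grouped
into one step, matching scikit-learn's average precision.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

logger = logging.getLogger(__name__)

__all__ = [
    "BenchmarkResult",
    "auc",
    "aupr_ratio",
    "f1_at_k",
    "f1_quantile_grid",
    "stratified_cis_benchmark",
]


@dataclass
class BenchmarkResult:
    metric: str
    value: float
    n_pos: int
    n_total: int
    stratum: str = ""


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(bool).ravel()
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if not np.isfinite(scores).all():
        raise ValueError("scores contain non-finite values")
    return scores, labels


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney with tie correction)."""
    scores, labels = _validate(scores, labels)
    if labels.all() or not labels.any():
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr_ratio(scores, labels) -> float:
    """Step-wise AUPR divided by the positive fraction (random-predictor AUPR)."""
    scores, labels = _validate(scores, labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR ratio needs at least one positive")
    ap = average_precision_score(labels, scores)
    return float(ap / (n_pos / labels.size))


def f1_at_k(predicted, truth, k: int | None = None) -> float:
    """F1 of a predicted set (or top-k of a ranking) against a truth set.

    ``predicted`` is either an iterable of ids (used as-is) or a mapping/
    series of id -> score from which the top ``k`` ids are taken (ties by
    id for determinism).
    """
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty")
    if hasattr(predicted, "items"):
        if k is None or k < 1:
            raise ValueError("k >= 1 required for ranked input")
        ranked = sorted(predicted.items(), key=lambda kv: (-kv[1], kv[0]))
        pred = {name for name, _ in ranked[:k]}
    else:
        pred = set(predicted)
        if k is not None:
            raise ValueError("k applies only to ranked (mapping) input")
    tp = len(pred & truth)
    if tp == 0:
        return 0.0
    precision = tp / len(pred)
    recall = tp / len(truth)
    return 2 * precision * recall / (precision + recall)


def f1_quantile_grid(scores: dict, truth, quantiles=None) -> list[BenchmarkResult]:
    """F1 at top-k cutoffs where k spans the 10th-90th score percentiles."""
    if quantiles is None:
        quantiles = [q / 10 for q in range(1, 10)]
    n = len(scores)
    out = []
    for q in quantiles:
        k = max(1, int(round((1 - q) * n)))  # q-th percentile cutoff keeps top (1-q)
        out.append(
            BenchmarkResult(
                metric="f1",
                value=f1_at_k(scores, truth, k=k),
                n_pos=len(set(truth)),
                n_total=n,
                stratum=f"q{int(q*100)}",
            )
        )
    return out


def stratified_cis_benchmark(
    scores, labels, distances, bin_edges=None
) -> list[BenchmarkResult]:
    """AUC and AUPR ratio of RE-TG scores per TSS-distance bin.

    Bins are half-open [lo, hi) over ``bin_edges`` (default 0-5, 5-25, 25-50,
    50-100, 100-200, 200-1000 kb) and partition the pairs exactly; strata
    lacking both classes are skipped with a log message.
    """
    scores, labels = _validate(scores, labels)
    distances = np.asarray(distances, dtype=float).ravel()
    if distances.shape != scores.shape:
        raise ValueError("distances must align with scores")
    if bin_edges is None:
        bin_edges = [0, 5_000, 25_000, 50_000, 100_000, 200_000, 1_000_000]
    results = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        mask = (distances >= lo) & (distances < hi)
        name = f"{lo//1000}-{hi//1000}kb"
        n_pos = int(labels[mask].sum())
        if mask.sum() == 0 or n_pos == 0 or n_pos == mask.sum():
            logger.info("distance bin %s skipped (n=%d, n_pos=%d)", name, mask.sum(), n_pos)
            continue
        results.append(
            BenchmarkResult("auc", auc(scores[mask], labels[mask]), n_pos, int(mask.sum()), name)
        )
        results.append(
            BenchmarkResult(
                "aupr_ratio", aupr_ratio(scores[mask], labels[mask]), n_pos, int(mask.sum()), name
            )
        )
    return results
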