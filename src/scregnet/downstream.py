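"""Downstream analyses on inferred GRNs.

Three families: (1) GWAS trait integration — SNP-to-gene linking within a
200-kb window, per-TF trait-regulation scores from trans-potential target
sets, cell-type enrichment and key-TF ranking; (2) regulon activity — a
rank-based recovery-curve enrichment of each TF's target set
in expression-only profiles, with differential activity between conditions;
(3) in silico TF knockout — zeroing TF expression at the input of the
trained per-gene models and reading off the predicted expression change.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import GeneAnnotation, GWASSummary

logger = logging.getLogger(__name__)

__all__ = [
    "map_snps_to_genes",
    "trait_regulation_score",
    "celltype_trait_enrichment",
    "rank_key_tfs",
    "quantile_normalize",
    "regulon_activity",
    "differential_activity",
    "in_silico_knockout",
]


def map_snps_to_genes(
    gwas: GWASSummary,
    genes: GeneAnnotation,
    window_bp: int = 200_000,
    trait_p: float = 0.01,
) -> tuple[pd.DataFrame, list[str]]:
    """Assign each gene the most significant p of SNPs within the linking window.

    A SNP links to a gene when the TSS lies inside the ``window_bp`` region
    centered on the SNP (|TSS - pos| <= window_bp/2). Gene-level p-values are
    Benjamini-Hochberg adjusted; the trait gene set is adjusted p < ``trait_p``.
    Genes with no linked SNP keep p = 1. Returns (per-gene table, trait genes).
    """
    half = window_bp // 2
    snp = gwas.table.sort_values("snp_id").reset_index(drop=True)  # order-invariant
    out = genes.table[["gene_id", "chrom", "tss"]].copy()
    pvals = np.ones(len(out))
    n_links = np.zeros(len(out), dtype=int)
    for chrom, snps in snp.groupby("chrom"):
        on = out["chrom"] == chrom
        if not on.any():
            continue
        tss = out.loc[on, "tss"].to_numpy()[:, None]
        pos = snps["pos"].to_numpy()[None, :]
        linked = np.abs(tss - pos) <= half
        p = np.where(linked, snps["pvalue"].to_numpy()[None, :], 1.0).min(axis=1)
        pvals[on.to_numpy()] = p
        n_links[on.to_numpy()] = linked.sum(axis=1)
    out["pvalue"] = pvals
    out["n_linked_snps"] = n_links
    out["p_adj"] = multipletests(pvals, method="fdr_bh")[1]
    trait_genes = out.loc[out["p_adj"] < trait_p, "gene_id"].tolist()
    return out, trait_genes


def trait_regulation_score(
    trp: pd.DataFrame,
    trait_genes: list[str],
    n_top: int = 1000,
) -> pd.DataFrame:
    """Overlap of each TF's top trans-potential targets with the trait set.

    ``trp`` is TF x TG. Per TF the ``n_top`` highest-TRP genes (all genes,
    with a log, when fewer exist) are intersected with the trait genes; the
    z-score standardizes counts across TFs (all-equal counts give z = 0).
    """
    genes = list(trp.columns)
    if n_top > len(genes):
        logger.info("n_top=%d exceeds %d genes; using all genes", n_top, len(genes))
        n_top = len(genes)
    trait = set(trait_genes)
    counts = {}
    for tf in trp.index:
        top = trp.loc[tf].sort_values(ascending=False, kind="mergesort").index[:n_top]
        counts[tf] = len(trait.intersection(top))
    out = pd.DataFrame({"overlap": pd.Series(counts)})
    sd = out["overlap"].std(ddof=0)
    out["z"] = 0.0 if sd == 0 else (out["overlap"] - out["overlap"].mean()) / sd
    return out


def celltype_trait_enrichment(
    overlap_counts: pd.Series,
    tf_expression: pd.Series,
    n: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided t-test: top-expressed TFs' overlap counts vs random TFs'.

    Returns (t, p). ``n`` shrinks with a warning when fewer than 2n TFs
    exist; degenerate variance gives p = 1.
    """
    tfs = overlap_counts.index
    if len(tfs) < 2 * n:
        n = max(1, len(tfs) // 2)
        logger.warning("fewer than 2n TFs; shrinking group size to %d", n)
    rng = np.random.default_rng(seed)
    top = tf_expression.reindex(tfs).sort_values(ascending=False).index[:n]
    random_tfs = rng.choice(tfs, size=n, replace=False)
    a = overlap_counts.loc[top].to_numpy(dtype=float)
    b = overlap_counts.loc[random_tfs].to_numpy(dtype=float)
    if np.std(a) == 0 and np.std(b) == 0:
        logger.info("degenerate variance in trait enrichment; p = 1")
        return 0.0, 1.0
    t, p = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
    return float(t), float(p)


def rank_key_tfs(expression_z: pd.Series, regulation_z: pd.Series) -> pd.DataFrame:
    """Key-TF ranking by expression z + trait-regulation z (ties by tf_id)."""
    tfs = expression_z.index.union(regulation_z.index)
    score = expression_z.reindex(tfs).fillna(0.0) + regulation_z.reindex(tfs).fillna(0.0)
    out = pd.DataFrame(
        {
            "tf_id": tfs,
            "expression_z": expression_z.reindex(tfs).to_numpy(),
            "regulation_z": regulation_z.reindex(tfs).to_numpy(),
            "score": score.to_numpy(),
        }
    )
    return out.sort_values(["score", "tf_id"], ascending=[False, True]).reset_index(drop=True)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Map every column onto the mean quantile profile (ties -> mean rank value)."""
    ranks = matrix.rank(method="average")
    sorted_cols = np.sort(matrix.to_numpy(), axis=0)
    reference = sorted_cols.mean(axis=1)  # mean of k-th order statistics
    # interpolate for fractional (tied) ranks
    grid = np.arange(1, matrix.shape[0] + 1, dtype=float)
    out = np.empty_like(matrix.to_numpy(), dtype=float)
    for j in range(matrix.shape[1]):
        out[:, j] = np.interp(ranks.iloc[:, j].to_numpy(), grid, reference)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def regulon_activity(
    trans_scores: pd.DataFrame,
    expression: pd.DataFrame,
    n_top: int = 1000,
    top_frac: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Rank-based target-set enrichment per sample (recovery-curve AUC).

    ``trans_scores`` is gene x TF; columns are quantile-normalized, then each
    TF's ``n_top`` top genes form its regulon. Per sample, genes are ranked
    by expression (descending) and the activity is the area under the curve
    of cumulative targets recovered within the top ``top_frac`` of the
    ranking, normalized by its maximum — in [0, 1] and invariant to monotone
    transforms of the expression. Returns (TF x sample activity, regulons).
    """
    shared = trans_scores.index.intersection(expression.index)
    if len(shared) < 0.5 * len(expression.index):
        raise ValueError(
            f"only {len(shared)}/{len(expression.index)} expression genes overlap the GRN"
        )
    scores = quantile_normalize(trans_scores.loc[shared])
    n_top = min(n_top, len(shared))
    regulons = {
        tf: scores[tf].sort_values(ascending=False, kind="mergesort").index[:n_top].tolist()
        for tf in scores.columns
    }
    expr = expression.loc[shared]
    n_genes = len(shared)
    cutoff = max(1, int(np.floor(top_frac * n_genes)))
    # rank positions per sample: 0 = highest expression (ties by stable order)
    order = np.argsort(-expr.to_numpy(), axis=0, kind="stable")
    position = np.empty_like(order)
    for j in range(order.shape[1]):
        position[order[:, j], j] = np.arange(n_genes)
    gene_pos = {g: i for i, g in enumerate(shared)}
    activity = pd.DataFrame(0.0, index=scores.columns, columns=expr.columns)
    for tf, targets in regulons.items():
        rows = [gene_pos[g] for g in targets]
        target_pos = position[rows]  # n_targets x n_samples
        inside = target_pos < cutoff
        # AUC of the step recovery curve = sum over target hits of (cutoff - pos)
        auc = np.where(inside, cutoff - target_pos, 0).sum(axis=0)
        denom = min(len(targets), cutoff)
        norm = np.arange(cutoff, cutoff - denom, -1).sum()  # best achievable
        activity.loc[tf] = auc / max(norm, 1)
    return activity, regulons


def differential_activity(activity: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Two-sided unpaired t-test per TF between two sample groups (BH q-values)."""
    groups = groups.reindex(activity.columns)
    labels = groups.dropna().unique()
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    a_cols = groups[groups == labels[0]].index
    b_cols = groups[groups == labels[1]].index
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs >= 2 samples")
    rows = []
    for tf in activity.index:
        a = activity.loc[tf, a_cols].to_numpy(dtype=float)
        b = activity.loc[tf, b_cols].to_numpy(dtype=float)
        if np.std(a) == 0 and np.std(b) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({"tf_id": tf, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def in_silico_knockout(
    models: dict,
    tf_set: list[str] | str,
    samples_by_gene: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Predicted expression change per gene after zeroing a TF (or TF set).

    ``models`` maps gene id to a fitted :class:`scregnet.pipeline.GeneModel`.
    The TF's raw expression is set to zero and pushed through each model's
    own log1p/standardization, so the intervention is on the measurement
    scale, not the z-score scale. Returns a gene x sample matrix of
    (perturbed - baseline) predictions; genes whose models do not use the TF
    change by exactly zero.
    """
    if isinstance(tf_set, str):
        tf_set = [tf_set]
    known = set()
    for model in models.values():
        known.update(model.spec.tf_ids)
    unknown = [t for t in tf_set if t not in known]
    if unknown:
        raise KeyError(f"unknown TF ids: {unknown}")
    rows = {}
    for gene_id, model in models.items():
        X = model.training_features if samples_by_gene is None else samples_by_gene[gene_id]
        base = model.predict_prepared(X)
        Xk = X.copy()
        for tf in tf_set:
            if tf in model.spec.tf_ids:
                k = model.spec.tf_ids.index(tf)
                Xk[:, k] = model.scaler.transform_raw_zero(k)
        rows[gene_id] = model.predict_prepared(Xk) - base
    return pd.DataFrame.from_dict(rows, orient="index")
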