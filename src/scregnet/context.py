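"""Cell-type-specific and cell-level GRNs from the population network.

The population GRN supplies context-independent quantities (trans strength
gamma, cis strength beta, binding strength alpha, motif binding affinity B,
RE-TG distance). Context (a cell type, or a single cell) contributes gene
expression and chromatin accessibility. The three potentials are

    TFB_kj = C_kj^{s_k} * E_k * O_j * (alpha_kj + B_kj)      TF -> RE
    CRP_ij = beta_ij * O_j * E_i * exp(-d_ij / d0)           RE -> TG
    TRP_ki = gamma_ki * sum_{j in S_i} TFB_kj * CRP_ij       TF -> TG

with d0 = 25 kb and S_i the 1-Mb candidate window of gene i. C_kj is the
TF-RE expression/accessibility correlation; s_k is the TF importance score,
measuring a TF's preference for activating cell-type-specific open
chromatin. C is clamped to [0,1] and s to >= 0 (0^0 := 1) and alpha + B is
floored at 0 so the potentials stay nonnegative.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BindingAffinity, CandidateWindow, MetacellData
from .grn import PopulationGRN
from .types import ExpressionMatrix, AccessibilityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ContextGRN",
    "celltype_specific_res",
    "motif_enrichment",
    "permutation_zscore",
    "tf_importance",
    "binding_potential",
    "cis_potential",
    "trans_potential",
    "build_celltype_grn",
    "build_cell_level_grns",
    "smooth_profiles",
]

DISTANCE_SCALE_BP = 25_000.0


@dataclass
class ContextGRN:
    """Potentials for one context (a cell type or one cell)."""

    context: str
    tfb: pd.DataFrame  # TF x RE
    crp: dict[str, pd.Series]  # gene -> RE-indexed cis potential
    trp: pd.DataFrame  # TF x TG

    def to_edge_frames(self) -> dict[str, pd.DataFrame]:
        tfb = self.tfb.stack().rename("score").reset_index()
        tfb.columns = ["source", "target", "score"]
        crp_rows = [
            {"source": re, "target": g, "score": v}
            for g, s in self.crp.items()
            for re, v in s.items()
        ]
        trp = self.trp.stack().rename("score").reset_index()
        trp.columns = ["source", "target", "score"]
        for df in (tfb, trp):
            df["context"] = self.context
        crp = pd.DataFrame(crp_rows, columns=["source", "target", "score"])
        crp["context"] = self.context
        return {"tfb": tfb, "crp": crp, "trp": trp}


def celltype_specific_res(
    accessibility: AccessibilityMatrix,
    type_of_column: dict[str, str],
    cell_type: str,
    n_top: int = 5000,
) -> list[str]:
    """Top REs by (mean accessibility in the type - mean in all other types).

    Ties break by re_id; if fewer REs exist than ``n_top`` all are returned.
    """
    types = pd.Series([type_of_column[c] for c in accessibility.col_ids])
    if types.nunique() < 2:
        raise ValueError("cell-type-specific REs need >= 2 cell types")
    O = accessibility.to_dense()
    inside = (types == cell_type).to_numpy()
    if not inside.any():
        raise ValueError(f"no columns of type {cell_type!r}")
    score = O[:, inside].mean(axis=1) - O[:, ~inside].mean(axis=1)
    order = sorted(zip(-score, accessibility.row_ids))
    if n_top > len(order):
        logger.info("requested %d specific REs but only %d exist", n_top, len(order))
    return [r for _, r in order[:n_top]]


def motif_enrichment(
    sites: np.ndarray,
    motif_ids: list[str],
    re_ids: list[str],
    specific_res: list[str],
) -> pd.Series:
    """One-sided hypergeometric p for motif-site overrepresentation.

    Universe = all REs; draws = the specific REs; successes = REs carrying at
    least one site of the motif. Motifs with no sites anywhere get p = 1.
    """
    sites = np.asarray(sites, dtype=bool)
    specific = np.isin(np.asarray(re_ids), np.asarray(specific_res))
    N, n = len(re_ids), int(specific.sum())
    pvals = {}
    for mi, mid in enumerate(motif_ids):
        K = int(sites[mi].sum())
        if K == 0:
            pvals[mid] = 1.0
            continue
        k = int(sites[mi][specific].sum())
        pvals[mid] = float(stats.hypergeom.sf(k - 1, N, K, n))
    return pd.Series(pvals, name="p_enrich")


def permutation_zscore(
    tf_expr: np.ndarray,
    accessibility: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """z-scored TF-RE Pearson correlation against a barcode-permutation null.

    ``tf_expr`` is one TF's expression across cells; ``accessibility`` is
    (n_re x n_cells). One shared permutation of the expression vector per
    iteration builds the per-pair null; zero-variance inputs give z = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t = np.asarray(tf_expr, dtype=float).ravel()
    A = np.atleast_2d(np.asarray(accessibility, dtype=float))
    if A.shape[1] != t.size:
        raise ValueError("accessibility columns must match the cell count")
    if t.size < 3:
        raise ValueError("need >= 3 cells for the correlation null")
    rng = np.random.default_rng(seed)
    t_c = t - t.mean()
    t_norm = np.linalg.norm(t_c)
    A_c = A - A.mean(axis=1, keepdims=True)
    A_norms = np.linalg.norm(A_c, axis=1)
    flat_re = A_norms < 1e-300
    if t_norm < 1e-300:
        return np.zeros(A.shape[0])
    safe = np.where(flat_re, 1.0, A_norms)
    r = (A_c @ t_c) / (safe * t_norm)
    null = np.empty((n_perm, A.shape[0]))
    for it in range(n_perm):
        null[it] = (A_c @ t_c[rng.permutation(t.size)]) / (safe * t_norm)
    sd = null.std(axis=0)
    z = np.where((sd > 0) & ~flat_re, (r - null.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def tf_importance(
    zscores: pd.DataFrame,
    enrichment_p: pd.Series,
    sites: np.ndarray,
    motif_ids: list[str],
    re_ids: list[str],
    pairs: list[tuple[str, str]],
    p_cut: float = 0.05,
) -> pd.Series:
    """TF importance s_k from motif enrichment and TF-RE co-activity.

    For a TF-motif pair (k, m): the co-activity z^co is the mean z_kj over
    REs carrying motif m; the pair score is z^co when motif m is enriched
    (p_m < p_cut), NA otherwise. s_k averages the non-NA pair scores and is
    0 when every pair is NA.
    """
    sites = np.asarray(sites, dtype=bool)
    motif_pos = {m: i for i, m in enumerate(motif_ids)}
    re_index = pd.Index(re_ids)
    z = zscores[re_index]
    scores: dict[str, list[float]] = {}
    for tf, motif in pairs:
        scores.setdefault(tf, [])
        if motif not in motif_pos or enrichment_p.get(motif, 1.0) >= p_cut:
            continue
        carrier = sites[motif_pos[motif]]
        if not carrier.any():
            continue
        if tf in z.index:
            scores[tf].append(float(z.loc[tf, re_index[carrier]].mean()))
    out = {tf: (float(np.mean(v)) if v else 0.0) for tf, v in scores.items()}
    return pd.Series(out, name="s_k")


def binding_potential(
    C: np.ndarray,
    s: np.ndarray,
    tf_expr_mean: np.ndarray,
    re_access_mean: np.ndarray,
    alpha: np.ndarray,
    B: np.ndarray,
) -> np.ndarray:
    """TFB_kj = clamp(C,0,1)^max(s,0) * E_k * O_j * max(alpha + B, 0); 0^0 = 1."""
    C = np.clip(np.asarray(C, float), 0.0, 1.0)
    s = np.maximum(np.asarray(s, float), 0.0)
    base = np.power(C, s[:, None])  # numpy: 0.0 ** 0.0 == 1.0
    affinity = np.maximum(np.asarray(alpha, float) + np.asarray(B, float), 0.0)
    return base * np.asarray(tf_expr_mean, float)[:, None] * np.asarray(re_access_mean, float)[None, :] * affinity


def cis_potential(
    beta: np.ndarray,
    re_access_mean: np.ndarray,
    gene_expr_mean: float,
    distances: np.ndarray,
    d0: float = DISTANCE_SCALE_BP,
) -> np.ndarray:
    """CRP_ij = beta_ij * O_j * E_i * exp(-d_ij / d0)."""
    d = np.asarray(distances, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    return np.asarray(beta, float) * np.asarray(re_access_mean, float) * float(gene_expr_mean) * np.exp(-d / d0)


def trans_potential(
    gamma: pd.DataFrame,
    tfb: pd.DataFrame,
    crp: dict[str, pd.Series],
) -> pd.DataFrame:
    """TRP_ki = gamma_ki * sum_{j in window(i)} TFB_kj * CRP_ij; empty window -> 0."""
    trp = pd.DataFrame(0.0, index=gamma.index, columns=gamma.columns)
    for gene in gamma.columns:
        series = crp.get(gene)
        if series is None or series.empty:
            continue
        cumulative = tfb[series.index].to_numpy() @ series.to_numpy()
        trp[gene] = gamma[gene].to_numpy() * cumulative
    return trp.fillna(0.0)


def smooth_profiles(values: np.ndarray, embedding: np.ndarray, k: int = 20) -> np.ndarray:
    """Average each column with its k nearest columns in the embedding.

    Dropout mitigation before computing TF-RE correlations on raw cells;
    metacell inputs are already averaged and skip this step.
    """
    from sklearn.neighbors import NearestNeighbors

    n = embedding.shape[0]
    k = min(k, n)
    _, nbrs = NearestNeighbors(n_neighbors=k).fit(embedding).kneighbors(embedding)
    return np.stack([values[:, idx].mean(axis=1) for idx in nbrs], axis=1)


def _pcc_matrix(E: np.ndarray, O: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between two matrices sharing columns."""
    Ec = E - E.mean(axis=1, keepdims=True)
    Oc = O - O.mean(axis=1, keepdims=True)
    en = np.linalg.norm(Ec, axis=1)
    on = np.linalg.norm(Oc, axis=1)
    en_safe = np.where(en < 1e-300, 1.0, en)
    on_safe = np.where(on < 1e-300, 1.0, on)
    corr = (Ec / en_safe[:, None]) @ (Oc / on_safe[:, None]).T
    corr[en < 1e-300, :] = 0.0
    corr[:, on < 1e-300] = 0.0
    return np.clip(corr, -1.0, 1.0)


@dataclass
class _SharedContext:
    """Cell-type-level quantities reused by every cell of the type."""

    C: np.ndarray  # TF x RE correlation
    s_k: pd.Series
    alpha: np.ndarray
    B: np.ndarray
    gamma: pd.DataFrame


def _shared_for_type(
    metacells: MetacellData,
    population: PopulationGRN,
    affinity: BindingAffinity,
    cell_type: str,
    sites: np.ndarray,
    motif_ids: list[str],
    pairs: list[tuple[str, str]],
    n_top_res: int,
    n_perm: int,
    seed: int,
    corr_scope: str,
) -> _SharedContext:
    tf_ids = population.tf_ids
    cols = (
        metacells.metacells_of_type(cell_type)
        if corr_scope == "within_type"
        else list(metacells.expression.col_ids)
    )
    E_tf = metacells.expression.subset_rows(tf_ids).subset_cols(cols).to_dense()
    O = metacells.accessibility.subset_cols(cols).to_dense()
    re_ids = metacells.accessibility.row_ids

    C = _pcc_matrix(E_tf, O)

    specific = celltype_specific_res(
        metacells.accessibility, metacells.metacell_types, cell_type, n_top=n_top_res
    )
    enrich = motif_enrichment(sites, motif_ids, re_ids, specific)
    spec_pos = [re_ids.index(r) for r in specific]
    zmat = np.stack(
        [
            permutation_zscore(E_tf[k], O[spec_pos], n_perm=n_perm, seed=seed + 17 * k)
            for k in range(len(tf_ids))
        ]
    )
    zdf = pd.DataFrame(zmat, index=tf_ids, columns=specific)
    site_cols = [re_ids.index(r) for r in specific]
    s_k = tf_importance(
        zdf, enrich, np.asarray(sites)[:, site_cols], motif_ids, specific, pairs
    ).reindex(tf_ids).fillna(0.0)

    alpha = population.alpha_matrix(re_ids).to_numpy()
    B = affinity.B[:, affinity.column_index(re_ids)]
    gamma = population.gamma_matrix()
    return _SharedContext(C=C, s_k=s_k, alpha=alpha, B=B, gamma=gamma)


def _potentials_for_profile(
    shared: _SharedContext,
    population: PopulationGRN,
    window: CandidateWindow,
    re_ids: list[str],
    tf_expr: np.ndarray,
    re_access: np.ndarray,
    gene_expr: pd.Series,
    context: str,
) -> ContextGRN:
    tfb = binding_potential(
        shared.C, shared.s_k.to_numpy(), tf_expr, re_access, shared.alpha, shared.B
    )
    tfb_df = pd.DataFrame(tfb, index=population.tf_ids, columns=re_ids)
    re_pos = {r: j for j, r in enumerate(re_ids)}
    crp: dict[str, pd.Series] = {}
    for gene, beta in population.beta.items():
        if beta.empty:
            crp[gene] = pd.Series(dtype=float)
            continue
        idx = [re_pos[r] for r in beta.index]
        d = window.distances_of(gene)
        vals = cis_potential(beta.to_numpy(), re_access[idx], float(gene_expr.get(gene, 0.0)), d)
        crp[gene] = pd.Series(vals, index=beta.index)
    trp = trans_potential(shared.gamma.fillna(0.0), tfb_df, crp)
    return ContextGRN(context=context, tfb=tfb_df, crp=crp, trp=trp)


def build_celltype_grn(
    metacells: MetacellData,
    population: PopulationGRN,
    affinity: BindingAffinity,
    window: CandidateWindow,
    sites: np.ndarray,
    motif_ids: list[str],
    pairs: list[tuple[str, str]],
    cell_type: str,
    n_top_res: int = 5000,
    n_perm: int = 1000,
    seed: int = 0,
    corr_scope: str = "within_type",
) -> ContextGRN:
    """Cell-type-specific GRN: potentials from type-averaged profiles."""
    shared = _shared_for_type(
        metacells, population, affinity, cell_type, sites, motif_ids, pairs,
        n_top_res, n_perm, seed, corr_scope,
    )
    cols = metacells.metacells_of_type(cell_type)
    E = metacells.expression.subset_cols(cols).to_dense().mean(axis=1)
    gene_expr = pd.Series(E, index=metacells.expression.row_ids)
    tf_expr = gene_expr.reindex(population.tf_ids).to_numpy()
    re_access = metacells.accessibility.subset_cols(cols).to_dense().mean(axis=1)
    return _potentials_for_profile(
        shared, population, window, metacells.accessibility.row_ids,
        tf_expr, re_access, gene_expr, cell_type,
    )


def build_cell_level_grns(
    expression: ExpressionMatrix,
    accessibility: AccessibilityMatrix,
    cell_types: dict[str, str],
    metacells: MetacellData,
    population: PopulationGRN,
    affinity: BindingAffinity,
    window: CandidateWindow,
    sites: np.ndarray,
    motif_ids: list[str],
    pairs: list[tuple[str, str]],
    cell_ids: list[str] | None = None,
    n_top_res: int = 5000,
    n_perm: int = 1000,
    seed: int = 0,
    corr_scope: str = "within_type",
) -> dict[str, ContextGRN]:
    """Per-cell GRNs: cell-level E/O with type-level C and s_k.

    The correlation C and importance s_k are estimated once per cell type
    (they need a population of samples) and shared by that type's cells.
    """
    if cell_ids is None:
        cell_ids = list(expression.col_ids)
    unknown = [c for c in cell_ids if c not in cell_types]
    if unknown:
        raise KeyError(f"unknown cell ids: {unknown[:5]}")
    shared_by_type: dict[str, _SharedContext] = {}
    out: dict[str, ContextGRN] = {}
    re_ids = list(accessibility.row_ids)
    for cell in cell_ids:
        ct = cell_types[cell]
        if ct not in shared_by_type:
            shared_by_type[ct] = _shared_for_type(
                metacells, population, affinity, ct, sites, motif_ids, pairs,
                n_top_res, n_perm, seed, corr_scope,
            )
        gene_expr = pd.Series(
            np.asarray(expression.to_dense()[:, expression.col_ids.index(cell)]).ravel(),
            index=expression.row_ids,
        )
        tf_expr = gene_expr.reindex(population.tf_ids).to_numpy()
        re_access = np.asarray(
            accessibility.to_dense()[:, accessibility.col_ids.index(cell)]
        ).ravel()
        out[cell] = _potentials_for_profile(
            shared_by_type[ct], population, window, re_ids,
            tf_expr, re_access, gene_expr, cell,
        )
    return out
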