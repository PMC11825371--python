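"""Metacell construction, candidate-RE windows and PWM binding affinity.

Metacells follow the square-root rule: per annotated cell type,
ceil(sqrt(n)) seed cells are sampled and each is replaced by the average of
its k nearest neighbours (k = 100 by default) in a 50-component PCA of the
log1p, depth-normalized expression. Neighbours may cross cell-type labels
unless ``within_type=True``.

Motif scanning is a log2-odds PWM scan against a uniform background on both
strands, replacing an external motif-scan binary: the binding affinity of a
TF for an RE is the best positional score of any of its paired motifs,
floored at zero so affinities are nonnegative edge weights.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .types import AccessibilityMatrix, CellAnnotation, ExpressionMatrix, GeneAnnotation, MotifLibrary, RegionSet

logger = logging.getLogger(__name__)

__all__ = [
    "MetacellData",
    "BindingAffinity",
    "CandidateWindow",
    "build_metacells",
    "assign_candidate_res",
    "compute_binding_affinity",
    "find_motif_sites",
    "max_pwm_score",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class MetacellData:
    expression: ExpressionMatrix  # genes x metacells
    accessibility: AccessibilityMatrix  # REs x metacells
    metacell_types: dict[str, str]  # metacell id -> cell type
    members: dict[str, list[str]]  # metacell id -> member cell ids

    @property
    def cell_types(self) -> list[str]:
        return sorted(set(self.metacell_types.values()))

    def metacells_of_type(self, cell_type: str) -> list[str]:
        return [m for m, t in self.metacell_types.items() if t == cell_type]


@dataclass
class BindingAffinity:
    """Nonnegative TF x RE binding affinity from the PWM scan."""

    B: np.ndarray
    tf_ids: list[str]
    re_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if (self.B < 0).any():
            raise ValueError("binding affinities must be >= 0")
        if self.B.shape != (len(self.tf_ids), len(self.re_ids)):
            raise ValueError("affinity shape does not match id lists")

    def column_index(self, re_ids) -> np.ndarray:
        pos = {r: j for j, r in enumerate(self.re_ids)}
        return np.array([pos[r] for r in re_ids], dtype=int)


@dataclass
class CandidateWindow:
    """Per gene: ordered (re_id, distance bp) pairs within the cis window."""

    mapping: dict[str, list[tuple[str, int]]]
    window_bp: int

    def res_of(self, gene_id: str) -> list[tuple[str, int]]:
        return self.mapping.get(gene_id, [])

    def re_ids_of(self, gene_id: str) -> list[str]:
        return [r for r, _ in self.res_of(gene_id)]

    def distances_of(self, gene_id: str) -> np.ndarray:
        return np.array([d for _, d in self.res_of(gene_id)], dtype=float)


def build_metacells(
    expression: ExpressionMatrix,
    accessibility: AccessibilityMatrix,
    cells: CellAnnotation,
    k_neighbors: int = 100,
    seed: int = 0,
    n_pcs: int = 50,
    within_type: bool = False,
) -> MetacellData:
    """Average each sampled seed cell with its nearest neighbours.

    Neighbourhoods are Euclidean in the top ``n_pcs`` principal components of
    log1p(counts normalized to 10^4 per cell); the seed cell itself is always
    a member. Raw expression and accessibility are averaged, so identical
    cells yield the common profile exactly.
    """
    if k_neighbors < 1:
        raise ValueError("k_neighbors must be >= 1")
    rng = np.random.default_rng(seed)
    E = expression.to_dense()
    O = accessibility.to_dense()
    if expression.col_ids != accessibility.col_ids:
        raise ValueError("expression and accessibility column ids differ")
    col_pos = {c: i for i, c in enumerate(expression.col_ids)}

    depth = np.maximum(E.sum(axis=0, keepdims=True), 1e-12)
    emb_input = np.log1p(E / depth * 1e4).T  # cells x genes
    n_comp = min(n_pcs, emb_input.shape[0] - 1, emb_input.shape[1])
    if n_comp >= 1:
        emb = PCA(n_components=n_comp, svd_solver="full", random_state=0).fit_transform(emb_input)
    else:
        emb = emb_input

    meta_expr, meta_acc = [], []
    metacell_types: dict[str, str] = {}
    members: dict[str, list[str]] = {}
    for cell_type in cells.cell_types:
        type_cells = cells.cells_of_type(cell_type)
        pool = type_cells if within_type else expression.col_ids
        pool_ix = np.array([col_pos[c] for c in pool])
        k = min(k_neighbors, len(pool))
        nn = NearestNeighbors(n_neighbors=k).fit(emb[pool_ix])
        n_meta = math.ceil(math.sqrt(len(type_cells)))
        seeds = rng.choice(len(type_cells), size=n_meta, replace=False)
        for s, seed_local in enumerate(sorted(seeds)):
            seed_global = col_pos[type_cells[seed_local]]
            _, nbrs = nn.kneighbors(emb[seed_global][None, :])
            member_ix = pool_ix[nbrs[0]]
            mid = f"{cell_type}_mc{s+1}"
            meta_expr.append(E[:, member_ix].mean(axis=1))
            meta_acc.append(O[:, member_ix].mean(axis=1))
            metacell_types[mid] = cell_type
            members[mid] = [expression.col_ids[i] for i in member_ix]

    meta_ids = list(metacell_types)
    return MetacellData(
        expression=ExpressionMatrix(np.column_stack(meta_expr), expression.row_ids, meta_ids),
        accessibility=AccessibilityMatrix(np.column_stack(meta_acc), accessibility.row_ids, meta_ids),
        metacell_types=metacell_types,
        members=members,
    )


def assign_candidate_res(
    genes: GeneAnnotation, regions: RegionSet, window_bp: int = 1_000_000
) -> CandidateWindow:
    """REs whose midpoint lies within ``window_bp`` of the TSS (closed bound).

    Distance d_ij = |RE midpoint - TSS|; per gene the list is ordered by
    (distance, re_id) so downstream feature orders are deterministic.
    """
    mids = regions.midpoints
    re_ids = np.asarray(regions.re_ids)
    re_chrom = regions.table["chrom"].to_numpy()
    mapping: dict[str, list[tuple[str, int]]] = {}
    for _, g in genes.table.iterrows():
        on_chrom = re_chrom == g["chrom"]
        d = np.abs(mids[on_chrom] - g["tss"])
        keep = d <= window_bp
        pairs = sorted(zip(d[keep].tolist(), re_ids[on_chrom][keep].tolist()))
        mapping[g["gene_id"]] = [(r, int(dd)) for dd, r in pairs]
    return CandidateWindow(mapping=mapping, window_bp=window_bp)


def _encode(seq: str) -> np.ndarray:
    out = np.full(len(seq), 4, dtype=np.int8)  # 4 = unknown base
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _log_odds(pwm: np.ndarray, pseudocount: float) -> np.ndarray:
    p = (pwm + pseudocount) / (1.0 + 4.0 * pseudocount)
    lo = np.log2(p / 0.25)
    # unknown bases contribute 0 (background probability)
    return np.vstack([lo, np.zeros((1, pwm.shape[1]))])


def _revcomp_log_odds(lo: np.ndarray) -> np.ndarray:
    return np.vstack([lo[:4][::-1, ::-1], lo[4:5, ::-1]])


def _best_score(lo: np.ndarray, encoded: np.ndarray) -> float:
    L = lo.shape[1]
    if len(encoded) < L:
        return -np.inf
    windows = sliding_window_view(encoded, L)  # n_pos x L
    fwd = lo[windows, np.arange(L)].sum(axis=1)
    rc = _revcomp_log_odds(lo)
    rev = rc[windows, np.arange(L)].sum(axis=1)
    return float(max(fwd.max(), rev.max()))


def max_pwm_score(pwm: np.ndarray, pseudocount: float = 1e-3) -> float:
    """Highest achievable log2-odds score: consensus base at every position."""
    lo = _log_odds(np.asarray(pwm, float), pseudocount)[:4]
    return float(lo.max(axis=0).sum())


def _scan_scores(
    motifs: MotifLibrary, sequences: dict[str, str], re_ids: list[str], pseudocount: float
) -> np.ndarray:
    """Best positional log2-odds score per (motif, RE), not floored."""
    scores = np.full((len(motifs.motif_ids), len(re_ids)), -np.inf)
    warned = False
    encoded = {}
    for r in re_ids:
        if r not in sequences:
            raise KeyError(f"no sequence provided for RE {r}")
        enc = _encode(sequences[r])
        if (enc == 4).any() and not warned:
            logger.warning("sequences contain non-ACGT bases; treated as background")
            warned = True
        encoded[r] = enc
    for mi, mid in enumerate(motifs.motif_ids):
        lo = _log_odds(motifs.pwms[mid], pseudocount)
        for ri, r in enumerate(re_ids):
            scores[mi, ri] = _best_score(lo, encoded[r])
    return scores


def compute_binding_affinity(
    motifs: MotifLibrary,
    regions: RegionSet,
    sequences: dict[str, str],
    pseudocount: float = 1e-3,
    tf_ids: list[str] | None = None,
) -> BindingAffinity:
    """B_kj = max over TF k's motifs of the best positional score in RE j, floored at 0."""
    re_ids = regions.re_ids
    scores = np.maximum(_scan_scores(motifs, sequences, re_ids, pseudocount), 0.0)
    if tf_ids is None:
        tf_ids = motifs.tf_ids
    motif_pos = {m: i for i, m in enumerate(motifs.motif_ids)}
    B = np.zeros((len(tf_ids), len(re_ids)))
    for ki, tf in enumerate(tf_ids):
        own = [motif_pos[m] for m in motifs.motifs_of_tf(tf)]
        if own:
            B[ki] = scores[own].max(axis=0)
    return BindingAffinity(
        B=B,
        tf_ids=list(tf_ids),
        re_ids=list(re_ids),
        provenance={"pseudocount": pseudocount, "background": "uniform", "strands": "both"},
    )


def find_motif_sites(
    motifs: MotifLibrary,
    regions: RegionSet,
    sequences: dict[str, str],
    rel_threshold: float = 0.8,
    pseudocount: float = 1e-3,
) -> np.ndarray:
    """Boolean motif x RE site calls.

    A site is called when the best positional score reaches ``rel_threshold``
    times the motif's maximum achievable score.
    """
    scores = _scan_scores(motifs, sequences, regions.re_ids, pseudocount)
    maxima = np.array([max_pwm_score(motifs.pwms[m], pseudocount) for m in motifs.motif_ids])
    return scores >= rel_threshold * maxima[:, None]
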