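"""Synthetic paired multiome data with a planted regulatory network.

The generator emulates the forward model the inference assumes: transcription
factor (TF) activities drive regulatory-element (RE) accessibility through a
binding matrix, and target-gene (TG) expression is a nonlinear (softplus)
function of RE accessibility and TF activity. Observed single-cell counts are
Poisson draws at a configurable library size; bulk samples are noisy
cell-type mixtures of the same network, giving the pre-training corpus the
cross-context diversity an atlas provides.

Every stochastic step draws from a single seeded :class:`numpy.random.
Generator`, so a config's ``seed`` fully determines the output.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AccessibilityMatrix,
    CellAnnotation,
    ExpressionMatrix,
    GeneAnnotation,
    GWASSummary,
    MotifLibrary,
    RegionSet,
)

__all__ = [
    "SimulationConfig",
    "PlantedNetwork",
    "SyntheticMultiome",
    "simulate_grn",
    "simulate_multiome",
    "simulate_gwas",
]

GENE_SPACING = 250_000  # bp between consecutive TSSs on the synthetic chromosome
RE_MAX_OFFSET = 100_000  # REs fall within this distance of their home TSS
RE_LENGTH = 200
MOTIF_LENGTH = 8


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; ``seed`` fully determines the output."""

    n_tf: int = 10
    n_gene: int = 60  # target genes (TF genes are additional expression rows)
    n_re: int = 200
    n_celltypes: int = 5
    cells_per_type: int = 200
    n_bulk: int = 150
    noise_sd: float = 0.1
    library_size: float = 5000.0  # mean total RNA counts per cell; 0 = no count sampling
    edge_density: float = 0.03
    motif_plant_rate: float = 0.9  # P(motif site | TF binds the RE)
    motif_fp_rate: float = 0.05  # P(motif site | TF does not bind): spurious scan hits
    count_model: str = "poisson"  # or "negative_binomial"
    nb_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_tf", "n_gene", "n_re", "n_celltypes", "cells_per_type", "n_bulk"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.edge_density <= 1):
            raise ValueError("edge_density must be in (0, 1]")
        if self.noise_sd < 0 or self.library_size < 0:
            raise ValueError("noise_sd and library_size must be >= 0")
        if self.count_model not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown count_model {self.count_model!r}")


@dataclass
class PlantedNetwork:
    """Ground-truth regulatory structure used to score recovery."""

    tf_ids: list[str]
    gene_ids: list[str]  # target genes only
    re_ids: list[str]
    true_alpha: np.ndarray  # TF x RE binding strength, >= 0
    true_beta: np.ndarray  # RE x TG cis effect
    true_gamma: np.ndarray  # TF x TG direct trans effect, >= 0
    genes: GeneAnnotation = None  # TF genes + target genes
    regions: RegionSet = None
    motifs: MotifLibrary = None
    sequences: dict[str, str] = field(default_factory=dict)
    candidate_res: dict[str, list[str]] = field(default_factory=dict)

    def trans_truth(self) -> np.ndarray:
        """Boolean TF x TG matrix: edge iff direct gamma or an alpha->beta RE path."""
        via_re = (self.true_alpha > 0).astype(float) @ (self.true_beta > 0).astype(float)
        return (self.true_gamma > 0) | (via_re > 0)


@dataclass
class SyntheticMultiome:
    """Paired single-cell + bulk fixtures drawn from one planted network."""

    expression: ExpressionMatrix  # (TF genes + TGs) x cells, counts
    accessibility: AccessibilityMatrix  # REs x cells
    cells: CellAnnotation
    bulk_expression: ExpressionMatrix  # genes x bulk samples, continuous
    bulk_accessibility: AccessibilityMatrix


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sharp_pwm(consensus: np.ndarray, p_consensus: float = 0.85) -> np.ndarray:
    pwm = np.full((4, len(consensus)), (1 - p_consensus) / 3)
    pwm[consensus, np.arange(len(consensus))] = p_consensus
    return pwm


def simulate_grn(config: SimulationConfig) -> PlantedNetwork:
    """Plant a TF->RE->TG network with motif evidence correlated to binding.

    TSSs sit every 250 kb on one synthetic chromosome (TF genes first); each
    RE is placed within 100 kb of a uniformly chosen home TG, so every RE lies
    inside at least one gene's 1-Mb candidate window. Motif evidence is
    informative but imperfect, as in real scans: a bound (TF, RE) pair
    carries the TF's consensus with probability ``motif_plant_rate`` and an
    unbound pair with probability ``motif_fp_rate`` — the structure the
    manifold regularization assumes, plus the noise that limits how hard it
    can be leaned on.
    """
    rng = np.random.default_rng(config.seed)
    n_tf, n_tg, n_re = config.n_tf, config.n_gene, config.n_re
    tf_ids = [f"TF{k+1}" for k in range(n_tf)]
    tg_ids = [f"G{i+1}" for i in range(n_tg)]
    all_ids = tf_ids + tg_ids

    tss = 100_000 + GENE_SPACING * np.arange(n_tf + n_tg)
    strand = np.where(np.arange(n_tf + n_tg) % 2 == 0, "+", "-")
    genes = GeneAnnotation(
        pd.DataFrame({"gene_id": all_ids, "chrom": "chr1", "tss": tss, "strand": strand})
    )

    # REs near a home target gene; positions unique by construction of offsets
    home = rng.integers(0, n_tg, size=n_re)
    offsets = rng.integers(-RE_MAX_OFFSET, RE_MAX_OFFSET + 1, size=n_re)
    centers = tss[n_tf + home] + offsets
    starts = np.maximum(centers - RE_LENGTH // 2, 0)
    re_ids = [f"RE{j+1}" for j in range(n_re)]
    regions = RegionSet(
        pd.DataFrame(
            {"re_id": re_ids, "chrom": "chr1", "start": starts, "end": starts + RE_LENGTH}
        )
    )

    # binding: each TF binds each RE with prob edge_density
    alpha_mask = rng.random((n_tf, n_re)) < config.edge_density
    if not alpha_mask.any():
        raise ValueError("edge_density infeasible: no TF-RE edges drawn at this size")
    true_alpha = alpha_mask * rng.uniform(0.5, 1.5, size=(n_tf, n_re))

    # cis: each RE regulates its home gene with prob 0.8
    true_beta = np.zeros((n_re, n_tg))
    cis_mask = rng.random(n_re) < 0.8
    true_beta[cis_mask, home[cis_mask]] = rng.uniform(0.5, 1.5, size=cis_mask.sum())

    # direct trans edges
    gamma_mask = rng.random((n_tf, n_tg)) < config.edge_density
    true_gamma = gamma_mask * rng.uniform(0.5, 1.5, size=(n_tf, n_tg))

    # motifs: one sharp PWM per TF plus two unpaired decoys
    consensus = {t: rng.integers(0, 4, size=MOTIF_LENGTH) for t in tf_ids}
    pwms = {f"M_{t}": _sharp_pwm(consensus[t]) for t in tf_ids}
    for d in range(2):
        pwms[f"M_decoy{d+1}"] = _sharp_pwm(rng.integers(0, 4, size=MOTIF_LENGTH))
    pairs = [(t, f"M_{t}") for t in tf_ids]
    motifs = MotifLibrary(pwms, pairs)

    bases = np.array(list("ACGT"))
    sequences = {}
    for j, rid in enumerate(re_ids):
        seq = rng.integers(0, 4, size=RE_LENGTH)
        for k in range(n_tf):
            bound = true_alpha[k, j] > 0
            rate = config.motif_plant_rate if bound else config.motif_fp_rate
            if rng.random() < rate:
                pos = rng.integers(0, RE_LENGTH - MOTIF_LENGTH + 1)
                seq[pos : pos + MOTIF_LENGTH] = consensus[tf_ids[k]]
        sequences[rid] = "".join(bases[seq])

    from .preprocess import assign_candidate_res  # deferred: avoids import cycle

    window = assign_candidate_res(genes, regions)
    candidate = {g: [r for r, _ in window.res_of(g)] for g in all_ids}

    return PlantedNetwork(
        tf_ids=tf_ids,
        gene_ids=tg_ids,
        re_ids=re_ids,
        true_alpha=true_alpha,
        true_beta=true_beta,
        true_gamma=true_gamma,
        genes=genes,
        regions=regions,
        motifs=motifs,
        sequences=sequences,
        candidate_res=candidate,
    )


def _forward_rates(network: PlantedNetwork, tf_act: np.ndarray, noise_sd: float, rng):
    """TF activities (n_tf x n) -> (RE accessibility rates, TG expression rates)."""
    n = tf_act.shape[1]
    eps_a = noise_sd * rng.standard_normal((len(network.re_ids), n)) if noise_sd else 0.0
    access = _softplus(network.true_alpha.T @ tf_act - 1.0 + eps_a)
    eps_e = noise_sd * rng.standard_normal((len(network.gene_ids), n)) if noise_sd else 0.0
    tg = _softplus(network.true_beta.T @ access + network.true_gamma.T @ tf_act - 2.0 + eps_e)
    return access, tg


def _sample_counts(rates: np.ndarray, config: SimulationConfig, rng) -> np.ndarray:
    scale = config.library_size * rates / np.maximum(rates.sum(axis=0, keepdims=True), 1e-12)
    if config.count_model == "poisson":
        return rng.poisson(scale).astype(float)
    r = 1.0 / config.nb_dispersion
    p = r / (r + np.maximum(scale, 1e-12))
    return rng.negative_binomial(r, p).astype(float)


def simulate_multiome(network: PlantedNetwork, config: SimulationConfig) -> SyntheticMultiome:
    """Draw single-cell counts per cell type plus bulk mixture samples.

    Per cell type, TF mean activities are bimodal (on/off) to create type
    specificity; per cell, activities get multiplicative log-normal noise.
    ``library_size == 0`` disables count sampling and returns the underlying
    rates (the noise-free deterministic limit when ``noise_sd == 0``).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_tf = len(network.tf_ids)
    n_cells = config.n_celltypes * config.cells_per_type

    on = rng.random((config.n_celltypes, n_tf)) < 0.5
    type_means = np.where(
        on,
        rng.uniform(1.0, 3.0, size=on.shape),
        rng.uniform(0.05, 0.3, size=on.shape),
    )

    cell_ids, cell_types, tf_cols = [], [], []
    for t in range(config.n_celltypes):
        for c in range(config.cells_per_type):
            cell_ids.append(f"type{t+1}_cell{c+1}")
            cell_types.append(f"type{t+1}")
        noise = (
            np.exp(config.noise_sd * rng.standard_normal((n_tf, config.cells_per_type)))
            if config.noise_sd
            else np.ones((n_tf, config.cells_per_type))
        )
        tf_cols.append(type_means[t][:, None] * noise)
    tf_act = np.concatenate(tf_cols, axis=1)

    access, tg = _forward_rates(network, tf_act, config.noise_sd, rng)
    expr_rates = np.vstack([tf_act, tg])

    if config.library_size > 0:
        expr = _sample_counts(expr_rates, config, rng)
        atac = _sample_counts(access, config, rng)
    else:
        expr, atac = expr_rates, access

    all_gene_ids = network.tf_ids + network.gene_ids
    cells = CellAnnotation(pd.DataFrame({"cell_id": cell_ids, "cell_type": cell_types}))

    # bulk atlas: each sample mixes freshly resampled synthetic cell types,
    # so the corpus spans diverse contexts (full-rank TF variation) rather
    # than the handful of types present in the single-cell data
    n_ctx = 3
    ctx_on = rng.random((config.n_bulk, n_ctx, n_tf)) < 0.5
    ctx_means = np.where(
        ctx_on,
        rng.uniform(1.0, 3.0, size=ctx_on.shape),
        rng.uniform(0.05, 0.3, size=ctx_on.shape),
    )
    w = rng.dirichlet(np.ones(n_ctx), size=config.n_bulk)  # n_bulk x n_ctx
    bulk_tf = np.einsum("bc,bck->kb", w, ctx_means)  # n_tf x n_bulk
    if config.noise_sd:
        bulk_tf = bulk_tf * np.exp(config.noise_sd * rng.standard_normal(bulk_tf.shape))
    bulk_access, bulk_tg = _forward_rates(network, bulk_tf, config.noise_sd, rng)
    bulk_expr = np.vstack([bulk_tf, bulk_tg])
    bulk_ids = [f"bulk{n+1}" for n in range(config.n_bulk)]

    return SyntheticMultiome(
        expression=ExpressionMatrix(expr, all_gene_ids, cell_ids),
        accessibility=AccessibilityMatrix(atac, network.re_ids, cell_ids),
        cells=cells,
        bulk_expression=ExpressionMatrix(bulk_expr, all_gene_ids, bulk_ids),
        bulk_accessibility=AccessibilityMatrix(bulk_access, network.re_ids, bulk_ids),
    )


def simulate_gwas(
    network: PlantedNetwork,
    config: SimulationConfig,
    n_trait_genes: int = 15,
    snps_per_gene: int = 2,
    n_background: int = 300,
) -> tuple[GWASSummary, list[str], str]:
    """Plant a trait around one TF's strongest targets.

    The TF with the most true trans edges is the trait driver; its strongest
    targets (by total planted effect) are trait genes, each tagged by
    ``snps_per_gene`` SNPs with p ~ 10^-U(6,10) within 40 kb of the TSS (well
    inside the 200-kb linking window, and closer to no other TSS given the
    250-kb gene spacing). Background SNPs carry Uniform(0,1] p-values.

    Returns (summary, trait gene list, trait TF id).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    truth = network.trans_truth()
    trait_tf_ix = int(np.argmax(truth.sum(axis=1)))
    trait_tf = network.tf_ids[trait_tf_ix]

    effect = (
        network.true_gamma[trait_tf_ix]
        + (network.true_alpha[trait_tf_ix] > 0).astype(float) @ network.true_beta
    )
    order = np.argsort(-effect)
    target_ixs = [i for i in order if truth[trait_tf_ix, i]][:n_trait_genes]
    trait_genes = [network.gene_ids[i] for i in target_ixs]

    gtab = network.genes.table.set_index("gene_id")
    rows = []
    for g in trait_genes:
        tss = int(gtab.loc[g, "tss"])
        for s in range(snps_per_gene):
            pos = tss + int(rng.integers(-40_000, 40_001))
            p = 10.0 ** (-rng.uniform(6, 10))
            rows.append((f"rs_{g}_{s+1}", gtab.loc[g, "chrom"], max(pos, 0), p))
    chrom_end = int(network.genes.table["tss"].max()) + 200_000
    for s in range(n_background):
        pos = int(rng.integers(0, chrom_end))
        rows.append((f"rs_bg_{s+1}", "chr1", pos, float(1.0 - rng.random())))
    gwas = GWASSummary(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "pvalue"]))
    return gwas, trait_genes, trait_tf
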