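"""End-to-end orchestration: data preparation, training, extraction.

Feature preparation: inputs are log1p-transformed and z-scored per feature
across the samples of their own domain (bulk statistics for the bulk stage,
metacell statistics for refinement), making the L1 and consolidation
penalties comparable across features; targets are log1p expression. The
scaler is retained per gene model so interventions (in silico knockout) can
map raw zero expression through the same transform.

Per target gene: features = all TF genes (the gene itself excluded — self-
regulation is not modeled) followed by candidate REs within 1 Mb of the
TSS. Two training routes share the architecture: the consolidated route
pre-trains on bulk, estimates the Fisher information and refines on
metacells with the four-term loss; the single-cell-only route trains from
random initialization with MSE + L1 alone.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .attribution import GeneAttribution, shapley_attributions
from .grn import PopulationGRN, assemble_population_grn, tf_re_binding_strength
from .metrics import aupr_ratio
from .preprocess import (
    BindingAffinity,
    CandidateWindow,
    MetacellData,
    assign_candidate_res,
    build_metacells,
    compute_binding_affinity,
    find_motif_sites,
)
from .synthetic import PlantedNetwork, SimulationConfig, SyntheticMultiome, simulate_grn, simulate_multiome

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureScaler",
    "GeneModel",
    "TrainedModels",
    "prepare_features",
    "train_models",
    "extract_population_grn",
    "gamma_aupr_ratio",
    "run_synthetic_pipeline",
]

_VAR_EPS = 1e-10


@dataclass
class FeatureScaler:
    """Per-feature log1p + z-score transform with frozen statistics."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, raw: np.ndarray) -> "FeatureScaler":
        logged = np.log1p(np.asarray(raw, dtype=float))
        std = logged.std(axis=0)
        return cls(mean=logged.mean(axis=0), std=np.where(std < 1e-8, 1.0, std))

    def transform(self, raw: np.ndarray) -> np.ndarray:
        return (np.log1p(np.asarray(raw, dtype=float)) - self.mean) / self.std

    def transform_raw_zero(self, feature_index: int) -> float:
        """The standardized value corresponding to raw expression 0."""
        return float(-self.mean[feature_index] / self.std[feature_index])


@dataclass
class GeneModel:
    """A fitted per-gene model plus everything needed to interrogate it."""

    spec: nn.GeneModelSpec
    params: nn.ModelParams
    scaler: FeatureScaler
    training_features: np.ndarray  # prepared single-cell design matrix
    training_target: np.ndarray
    params_bulk: nn.ModelParams | None = None
    fisher: np.ndarray | None = None
    history: pd.DataFrame | None = None

    def predict_prepared(self, X: np.ndarray) -> np.ndarray:
        return nn.predict(self.spec, self.params, X)


@dataclass
class TrainedModels:
    models: dict[str, GeneModel]
    skipped: list[str] = field(default_factory=list)
    method: str = "consolidated"


def _feature_matrix(
    expression, accessibility, tf_ids: list[str], re_ids: list[str]
) -> np.ndarray:
    """Raw (samples x features) matrix: TF expression rows then RE rows."""
    parts = []
    if tf_ids:
        parts.append(expression.subset_rows(tf_ids).to_dense())
    if re_ids:
        parts.append(accessibility.subset_rows(re_ids).to_dense())
    return np.vstack(parts).T if parts else np.empty((len(expression.col_ids), 0))


def prepare_features(
    expression, accessibility, tf_ids: list[str], re_ids: list[str]
) -> tuple[np.ndarray, FeatureScaler]:
    raw = _feature_matrix(expression, accessibility, tf_ids, re_ids)
    scaler = FeatureScaler.fit(raw)
    return scaler.transform(raw), scaler


def _gene_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] & 0x7FFFFFFF)


def normalized_fisher(fisher: np.ndarray) -> np.ndarray:
    """Rescale the Fisher diagonal to unit mean.

    Raw squared-gradient magnitudes vary by orders of magnitude across genes
    (they scale with the residuals of the bulk fit), which would make any
    single consolidation weight vacuous for some genes and rigid for others;
    unit-mean scaling makes lambda4 comparable across genes. All-zero Fisher
    (a perfect bulk fit) is returned unchanged.
    """
    mean = fisher.mean()
    return fisher / mean if mean > 0 else fisher


def train_models(
    metacells: MetacellData,
    window: CandidateWindow,
    affinity: BindingAffinity,
    tf_ids: list[str],
    target_genes: list[str],
    bulk_expression=None,
    bulk_accessibility=None,
    weights: nn.LossWeights = nn.LossWeights(),
    method: str = "consolidated",
    epochs: int = 500,
    seed: int = 0,
    activation: str = "relu",
) -> TrainedModels:
    """Fit one model per target gene.

    ``method="consolidated"`` pre-trains on the bulk matrices and refines with the
    consolidated loss; ``method="single_cell"`` skips pre-training (bulk inputs may
    be None). Genes with near-zero target variance are skipped and logged.
    """
    if method not in ("consolidated", "single_cell"):
        raise ValueError(f"unknown method {method!r}")
    if method == "consolidated" and (bulk_expression is None or bulk_accessibility is None):
        raise ValueError("bulk matrices are required for the consolidated route")
    models: dict[str, GeneModel] = {}
    skipped: list[str] = []
    for gi, gene in enumerate(target_genes):
        gene_tfs = [t for t in tf_ids if t != gene]  # no self-regulation
        gene_res = window.re_ids_of(gene)
        spec = nn.GeneModelSpec(
            gene_id=gene,
            tf_ids=tuple(gene_tfs),
            re_ids=tuple(gene_res),
            activation=activation,
        )
        y_sc = np.log1p(metacells.expression.row(gene))
        if y_sc.var() < _VAR_EPS:
            logger.info("gene %s has near-zero expression variance; skipped", gene)
            skipped.append(gene)
            continue
        X_sc, scaler = prepare_features(
            metacells.expression, metacells.accessibility, gene_tfs, gene_res
        )
        gseed = _gene_seed(seed, gi)
        if method == "consolidated":
            X_bulk, _ = prepare_features(
                bulk_expression, bulk_accessibility, gene_tfs, gene_res
            )
            y_bulk = np.log1p(bulk_expression.row(gene))
            pre = nn.bulk_pretrain(
                spec, X_bulk, y_bulk, weights=weights, epochs=epochs, seed=gseed
            )
            B_gene = affinity.B[
                np.ix_(
                    [affinity.tf_ids.index(t) for t in gene_tfs],
                    affinity.column_index(gene_res) if gene_res else [],
                )
            ]
            fit = nn.consolidated_refine(
                spec, pre.params, normalized_fisher(pre.fisher), X_sc, y_sc, B_gene,
                weights=weights, epochs=epochs, seed=gseed,
            )
            models[gene] = GeneModel(
                spec=spec, params=fit.params, scaler=scaler,
                training_features=X_sc, training_target=y_sc,
                params_bulk=pre.params, fisher=pre.fisher, history=fit.history,
            )
        else:
            fit = nn.train_single_cell(
                spec, X_sc, y_sc, weights=weights, epochs=epochs, seed=gseed
            )
            models[gene] = GeneModel(
                spec=spec, params=fit.params, scaler=scaler,
                training_features=X_sc, training_target=y_sc, history=fit.history,
            )
    return TrainedModels(models=models, skipped=skipped, method=method)


def extract_population_grn(
    trained: TrainedModels,
    window: CandidateWindow,
    n_perm: int = 200,
    seed: int = 0,
) -> PopulationGRN:
    """Shapley attributions (beta, gamma) + embedding correlations (alpha)."""
    attributions: dict[str, GeneAttribution] = {}
    alphas = {}
    for gi, (gene, model) in enumerate(trained.models.items()):
        attributions[gene] = shapley_attributions(
            model.spec, model.params, model.training_features,
            n_perm=n_perm, seed=_gene_seed(seed, gi),
        )
        if model.spec.re_ids:
            alphas[gene] = tf_re_binding_strength(
                model.params, list(model.spec.tf_ids), list(model.spec.re_ids)
            )
    return assemble_population_grn(attributions, alphas, window, skipped=trained.skipped)


def gamma_aupr_ratio(population: PopulationGRN, network: PlantedNetwork) -> float:
    """AUPR ratio of trans strengths against the planted TF-TG truth."""
    gamma = population.gamma_matrix(network.gene_ids).reindex(network.tf_ids).fillna(0.0)
    truth = network.trans_truth()
    return aupr_ratio(gamma.to_numpy().ravel(), truth.ravel())


@dataclass
class PipelineResult:
    network: PlantedNetwork
    multiome: SyntheticMultiome
    metacells: MetacellData
    window: CandidateWindow
    affinity: BindingAffinity
    sites: np.ndarray
    trained: TrainedModels
    population: PopulationGRN


def run_synthetic_pipeline(
    config: SimulationConfig,
    method: str = "consolidated",
    weights: nn.LossWeights = nn.LossWeights(),
    epochs: int = 500,
    n_perm: int = 200,
    k_neighbors: int = 100,
    seed: int | None = None,
) -> PipelineResult:
    """Simulate, preprocess, train and extract a population GRN in one call."""
    seed = config.seed if seed is None else seed
    network = simulate_grn(config)
    multiome = simulate_multiome(network, config)
    metacells = build_metacells(
        multiome.expression, multiome.accessibility, multiome.cells,
        k_neighbors=k_neighbors, seed=seed,
    )
    window = assign_candidate_res(network.genes, network.regions)
    affinity = compute_binding_affinity(
        network.motifs, network.regions, network.sequences, tf_ids=network.tf_ids
    )
    sites = find_motif_sites(network.motifs, network.regions, network.sequences)
    trained = train_models(
        metacells, window, affinity, network.tf_ids, network.gene_ids,
        bulk_expression=multiome.bulk_expression,
        bulk_accessibility=multiome.bulk_accessibility,
        weights=weights, method=method, epochs=epochs, seed=seed,
    )
    population = extract_population_grn(trained, window, n_perm=n_perm, seed=seed)
    return PipelineResult(
        network=network, multiome=multiome, metacells=metacells, window=window,
        affinity=affinity, sites=sites, trained=trained, population=population,
    )
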