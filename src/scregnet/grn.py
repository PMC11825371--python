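"""Population-level GRN assembly from trained per-gene models.

Three scores per gene model:

* gamma (TF -> TG trans strength) and beta (RE -> TG cis strength): mean
  absolute Shapley value of the corresponding input features;
* alpha (TF -> RE binding strength): Pearson correlation between the
  first-layer weight rows (64-d embeddings) of the TF and RE features.

Gene-level alphas for a TF-RE pair seen in several gene windows are merged
by keeping the entry of maximum absolute value (sign preserved). Dominance
classification compares per-sample mean |Shapley| of RE features against TF
features with a two-sided unpaired t-test, Bonferroni-corrected across
genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import GeneAttribution
from .nn import ModelParams
from .preprocess import CandidateWindow

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationGRN",
    "tf_re_binding_strength",
    "assemble_population_grn",
    "classify_dominance",
]


@dataclass
class PopulationGRN:
    """alpha in [-1,1]; beta, gamma >= 0 (mean absolute attributions)."""

    tf_ids: list[str]
    alpha: pd.DataFrame  # columns tf, re, alpha
    beta: dict[str, pd.Series]  # gene -> RE-indexed cis strength
    gamma: dict[str, pd.Series]  # gene -> TF-indexed trans strength
    skipped: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.gamma)

    def gamma_matrix(self, gene_ids=None) -> pd.DataFrame:
        """TF x TG trans-strength matrix (absent genes -> NaN columns)."""
        genes = list(gene_ids) if gene_ids is not None else self.gene_ids
        mat = pd.DataFrame(np.nan, index=self.tf_ids, columns=genes)
        for g in genes:
            if g in self.gamma:
                mat.loc[self.gamma[g].index, g] = self.gamma[g].to_numpy()
        return mat

    def alpha_matrix(self, re_ids) -> pd.DataFrame:
        """TF x RE binding-strength matrix over ``re_ids`` (missing pairs -> 0)."""
        mat = pd.DataFrame(0.0, index=self.tf_ids, columns=list(re_ids))
        for row in self.alpha.itertuples(index=False):
            if row.re in mat.columns:
                mat.loc[row.tf, row.re] = row.alpha
        return mat


def tf_re_binding_strength(
    params: ModelParams, tf_ids, re_ids
) -> pd.DataFrame:
    """Pearson correlation of first-layer embeddings, alpha_kj in [-1, 1].

    Each feature's embedding is its row of W1 (length = first hidden layer).
    Zero-variance embeddings yield alpha = 0 with a warning.
    """
    tf_ids, re_ids = list(tf_ids), list(re_ids)
    W1 = np.asarray(params.W1, dtype=float)
    if W1.shape[0] != len(tf_ids) + len(re_ids):
        raise ValueError("W1 rows do not match TF + RE feature count")
    emb = W1 - W1.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(emb, axis=1)
    flat = norms < 1e-300
    if flat.any():
        logger.warning("%d features have zero-variance embeddings; alpha set to 0", flat.sum())
    safe = np.where(flat, 1.0, norms)
    unit = emb / safe[:, None]
    corr = unit[: len(tf_ids)] @ unit[len(tf_ids) :].T
    corr[flat[: len(tf_ids)], :] = 0.0
    corr[:, flat[len(tf_ids) :]] = 0.0
    corr = np.clip(corr, -1.0, 1.0)
    rows = [
        {"tf": tf, "re": re, "alpha": corr[k, j]}
        for k, tf in enumerate(tf_ids)
        for j, re in enumerate(re_ids)
    ]
    return pd.DataFrame(rows, columns=["tf", "re", "alpha"])


def assemble_population_grn(
    attributions: dict[str, GeneAttribution],
    alphas: dict[str, pd.DataFrame],
    window: CandidateWindow,
    skipped: list[str] | None = None,
) -> PopulationGRN:
    """Merge per-gene attributions and embeddings into one population GRN.

    ``attributions`` and ``alphas`` are keyed by gene id; TF-RE alpha entries
    shared by several genes keep the value of maximum absolute magnitude.
    """
    skipped = list(skipped or [])
    tf_ids: list[str] = []
    beta: dict[str, pd.Series] = {}
    gamma: dict[str, pd.Series] = {}
    best: dict[tuple[str, str], float] = {}
    for gene_id, attr in attributions.items():
        if not tf_ids:
            tf_ids = list(attr.tf_ids)
        elif list(attr.tf_ids) != tf_ids:
            raise ValueError(f"gene {gene_id} has a conflicting TF feature order")
        window_res = window.re_ids_of(gene_id)
        if list(attr.re_ids) != list(window_res):
            raise ValueError(f"gene {gene_id} RE features disagree with its candidate window")
        gamma[gene_id] = pd.Series(attr.gamma, index=list(attr.tf_ids), name=gene_id)
        beta[gene_id] = pd.Series(attr.beta, index=list(attr.re_ids), name=gene_id)
        if gene_id in alphas:
            for row in alphas[gene_id].itertuples(index=False):
                key = (row.tf, row.re)
                if key not in best or abs(row.alpha) > abs(best[key]):
                    best[key] = float(row.alpha)
    if skipped:
        logger.info("population GRN assembled without %d skipped genes", len(skipped))
    alpha = pd.DataFrame(
        [{"tf": k[0], "re": k[1], "alpha": v} for k, v in sorted(best.items())],
        columns=["tf", "re", "alpha"],
    )
    return PopulationGRN(tf_ids=tf_ids, alpha=alpha, beta=beta, gamma=gamma, skipped=skipped)


def classify_dominance(
    attributions: dict[str, GeneAttribution], alpha_level: float = 0.05
) -> pd.DataFrame:
    """Label each gene cis-, trans-dominant or neither.

    Per gene, the per-sample mean |Shapley| of RE features is compared with
    that of TF features (two-sided unpaired t-test); p-values are Bonferroni
    corrected across tested genes. Genes without RE features are 'neither'.
    """
    rows = []
    testable = [g for g, a in attributions.items() if len(a.re_ids) > 0 and a.phi.shape[0] >= 2]
    n_tests = len(testable)
    for gene_id, attr in attributions.items():
        if gene_id not in testable:
            logger.info("gene %s lacks RE features or samples; labeled neither", gene_id)
            rows.append({"gene_id": gene_id, "label": "neither", "p_raw": np.nan, "p_adj": np.nan})
            continue
        re_s, tf_s = attr.re_abs, attr.tf_abs
        if np.std(re_s) == 0 and np.std(tf_s) == 0:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(re_s, tf_s, equal_var=True)
        p_adj = min(1.0, float(p) * n_tests)  # Bonferroni
        if p_adj < alpha_level:
            label = "cis" if t > 0 else "trans"
        else:
            label = "neither"
        rows.append(
            {"gene_id": gene_id, "label": label, "p_raw": float(p), "p_adj": p_adj}
        )
    return pd.DataFrame(rows)
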