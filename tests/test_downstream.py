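"""GWAS linking, trait scores, regulon activity and in silico knockout."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scregnet.downstream import (
    celltype_trait_enrichment,
    differential_activity,
    in_silico_knockout,
    map_snps_to_genes,
    quantile_normalize,
    rank_key_tfs,
    regulon_activity,
    trait_regulation_score,
)
from scregnet.types import GeneAnnotation, GWASSummary


def _genes(tss_by_id: dict[str, int]) -> GeneAnnotation:
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": list(tss_by_id),
                "chrom": "chr1",
                "tss": list(tss_by_id.values()),
                "strand": "+",
            }
        )
    )


def _gwas(rows) -> GWASSummary:
    return GWASSummary(pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "pvalue"]))


class TestSnpMapping:
    def test_single_link_takes_snp_p(self):
        genes = _genes({"g": 1_000_000})
        gwas = _gwas([("s", "chr1", 1_050_000, 1e-8)])
        table, _ = map_snps_to_genes(gwas, genes)
        assert table.loc[0, "pvalue"] == 1e-8

    def test_window_boundary_is_100kb_each_side(self):
        genes = _genes({"inside": 1_000_000, "outside": 2_000_000})
        gwas = _gwas(
            [
                ("edge", "chr1", 1_100_000, 1e-9),  # exactly 100 kb -> linked
                ("past", "chr1", 2_100_001, 1e-9),  # 100,001 bp -> not linked
            ]
        )
        table, _ = map_snps_to_genes(gwas, genes)
        t = table.set_index("gene_id")
        assert t.loc["inside", "pvalue"] == 1e-9
        assert t.loc["outside", "pvalue"] == 1.0

    def test_most_significant_linked_snp_kept(self):
        genes = _genes({"g": 500_000})
        gwas = _gwas(
            [("a", "chr1", 480_000, 1e-4), ("b", "chr1", 520_000, 1e-8)]
        )
        table, _ = map_snps_to_genes(gwas, genes)
        assert table.loc[0, "pvalue"] == 1e-8

    def test_snp_order_invariance_and_idempotence(self):
        genes = _genes({f"g{i}": 200_000 * i + 100_000 for i in range(5)})
        rows = [(f"s{i}", "chr1", 150_000 * i + 90_000, 10.0 ** -(i + 2)) for i in range(6)]
        t1, set1 = map_snps_to_genes(_gwas(rows), genes)
        t2, set2 = map_snps_to_genes(_gwas(rows[::-1]), genes)
        assert t1["pvalue"].tolist() == t2["pvalue"].tolist() and set1 == set2

    def test_gene_without_chromosome_snps_unassigned(self):
        genes = _genes({"g": 100})
        gwas = _gwas([("s", "chrX", 100, 1e-9)])
        table, trait = map_snps_to_genes(gwas, genes)
        assert table.loc[0, "pvalue"] == 1.0 and trait == []


class TestTraitScores:
    def test_identical_counts_give_zero_z(self):
        trp = pd.DataFrame(
            np.ones((3, 6)), index=["t1", "t2", "t3"], columns=[f"g{i}" for i in range(6)]
        )
        out = trait_regulation_score(trp, ["g0", "g1"], n_top=6)
        assert (out["z"] == 0.0).all()

    def test_empty_trait_set_gives_zero_counts(self):
        rng = np.random.default_rng(0)
        trp = pd.DataFrame(rng.random((2, 5)), index=["a", "b"])
        out = trait_regulation_score(trp, [], n_top=3)
        assert (out["overlap"] == 0).all()

    def test_tf_with_trait_targets_on_top(self):
        genes = [f"g{i}" for i in range(20)]
        # bystander prefers the non-trait end of the gene list
        trp = pd.DataFrame(
            np.vstack([np.full(20, 0.1), np.linspace(0.1, 1.0, 20)]),
            index=["driver", "bystander"], columns=genes,
        )
        trait = genes[:5]
        trp.loc["driver", trait] = 5.0
        out = trait_regulation_score(trp, trait, n_top=5)
        assert out.loc["driver", "overlap"] == 5
        assert out.loc["driver", "z"] > out.loc["bystander", "z"]

    def test_enrichment_null_calibration(self):
        rng = np.random.default_rng(1)
        counts = pd.Series(rng.poisson(5, 40), index=[f"t{i}" for i in range(40)])
        expr = pd.Series(rng.random(40), index=counts.index)
        pvals = [
            celltype_trait_enrichment(counts, expr, n=10, seed=s)[1] for s in range(40)
        ]
        # counts independent of expression: p should not pile up near 0
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25

    def test_enrichment_detects_planted_shift(self):
        rng = np.random.default_rng(2)
        expr = pd.Series(rng.random(60), index=[f"t{i}" for i in range(60)])
        counts = pd.Series(rng.poisson(5, 60), index=expr.index)
        counts.loc[expr.sort_values(ascending=False).index[:20]] += 10
        t, p = celltype_trait_enrichment(counts, expr, n=20, seed=0)
        assert p < 1e-4

    def test_enrichment_shrinks_n_with_warning(self, caplog):
        counts = pd.Series([1, 2, 3], index=["a", "b", "c"])
        expr = pd.Series([3.0, 2.0, 1.0], index=["a", "b", "c"])
        with caplog.at_level("WARNING"):
            celltype_trait_enrichment(counts, expr, n=100, seed=0)
        assert "shrinking" in caplog.text

    def test_key_tf_ranking_and_ties(self):
        expr_z = pd.Series({"a": 2.0, "b": 3.0, "c": 1.0})
        reg_z = pd.Series({"a": 2.0, "b": 0.0, "c": 1.0})
        out = rank_key_tfs(expr_z, reg_z)
        assert out["tf_id"].tolist() == ["a", "b", "c"]
        tied = rank_key_tfs(
            pd.Series({"x": 1.0, "y": 1.0}), pd.Series({"x": 0.0, "y": 0.0})
        )
        assert tied["tf_id"].tolist() == ["x", "y"]


class TestRegulonActivity:
    def test_quantile_normalization_reference_profile(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(m)
        assert np.allclose(out["a"], [2.5, 3.5, 4.5])
        assert np.allclose(out["b"], [2.5, 3.5, 4.5])

    def test_targets_at_top_give_activity_one(self):
        genes = [f"g{i}" for i in range(40)]
        trans = pd.DataFrame({"tf": np.arange(40)[::-1]}, index=genes, dtype=float)
        expr = pd.DataFrame({"s": np.arange(40)[::-1]}, index=genes, dtype=float)
        act, regs = regulon_activity(trans, expr, n_top=2, top_frac=0.05)
        assert regs["tf"] == ["g0", "g1"]
        assert act.loc["tf", "s"] == pytest.approx(1.0)

    def test_random_expression_matches_permutation_null(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(200)]
        trans = pd.DataFrame({"tf": rng.random(200)}, index=genes)
        n_top, frac = 20, 0.1
        obs = []
        for s in range(150):
            expr = pd.DataFrame({"s": rng.permutation(200).astype(float)}, index=genes)
            obs.append(regulon_activity(trans, expr, n_top=n_top, top_frac=frac)[0].iloc[0, 0])
        # permutation oracle: same statistic computed by direct simulation
        cutoff = int(frac * 200)
        null = []
        targets = set(
            trans["tf"].sort_values(ascending=False, kind="mergesort").index[:n_top]
        )
        pos = {g: i for i, g in enumerate(genes)}
        for s in range(150):
            perm = rng.permutation(200)
            ranks = np.empty(200, dtype=int)
            ranks[perm] = np.arange(200)
            hits = sorted(ranks[pos[g]] for g in targets if ranks[pos[g]] < cutoff)
            auc = sum(cutoff - h for h in hits)
            norm = sum(range(cutoff, cutoff - min(n_top, cutoff), -1))
            null.append(auc / norm)
        assert abs(np.mean(obs) - np.mean(null)) < 3 * np.std(null) / np.sqrt(150) + 0.02

    def test_rank_invariance_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(60)]
        trans = pd.DataFrame(rng.random((60, 3)), index=genes, columns=["a", "b", "c"])
        expr = pd.DataFrame(rng.random((60, 4)), index=genes)
        act1, _ = regulon_activity(trans, expr, n_top=10)
        act2, _ = regulon_activity(trans, np.exp(5 * expr), n_top=10)
        assert np.allclose(act1.to_numpy(), act2.to_numpy())

    def test_low_gene_overlap_rejected(self):
        trans = pd.DataFrame({"tf": [1.0, 2.0]}, index=["g1", "g2"])
        expr = pd.DataFrame({"s": [1.0, 2.0, 3.0, 4.0, 5.0]}, index=[f"x{i}" for i in range(5)])
        with pytest.raises(ValueError, match="overlap"):
            regulon_activity(trans, expr)

    def test_differential_activity_cases(self):
        rng = np.random.default_rng(5)
        act = pd.DataFrame(
            np.vstack([np.r_[rng.random(4) * 0.01, rng.random(4) * 0.01 + 0.9],
                       np.full(8, 0.5)]),
            index=["shifted", "flat"],
            columns=[f"s{i}" for i in range(8)],
        )
        groups = pd.Series(["A"] * 4 + ["B"] * 4, index=act.columns)
        out = differential_activity(act, groups).set_index("tf_id")
        assert out.loc["shifted", "q"] < 0.05
        assert out.loc["flat", "p"] == 1.0
        with pytest.raises(ValueError, match="2 samples"):
            differential_activity(act, pd.Series(["A"] + ["B"] * 7, index=act.columns))
        with pytest.raises(ValueError, match="2 groups"):
            differential_activity(act, pd.Series(["A"] * 8, index=act.columns))


class TestKnockout:
    def test_unknown_tf_rejected(self, tiny_pipeline):
        with pytest.raises(KeyError, match="unknown TF"):
            in_silico_knockout(tiny_pipeline.trained.models, "NOT_A_TF")

    def test_delta_zero_for_models_not_using_tf(self, tiny_pipeline):
        models = tiny_pipeline.trained.models
        tf = tiny_pipeline.network.tf_ids[0]
        # synthesize a model copy whose spec drops the TF entirely
        gene, model = next(iter(models.items()))
        delta = in_silico_knockout({gene: model}, tf)
        k = model.spec.tf_ids.index(tf)
        x0 = model.training_features.copy()
        x0[:, k] = model.scaler.transform_raw_zero(k)
        expected = model.predict_prepared(x0) - model.predict_prepared(model.training_features)
        assert np.allclose(delta.loc[gene].to_numpy(), expected, atol=1e-12)

    def test_combination_knockout_zeroes_all_listed_tfs(self, tiny_pipeline):
        models = tiny_pipeline.trained.models
        tfs = tiny_pipeline.network.tf_ids[:2]
        delta_combo = in_silico_knockout(models, tfs)
        gene = next(iter(models))
        model = models[gene]
        x = model.training_features.copy()
        for tf in tfs:
            k = model.spec.tf_ids.index(tf)
            x[:, k] = model.scaler.transform_raw_zero(k)
        expected = model.predict_prepared(x) - model.predict_prepared(model.training_features)
        assert np.allclose(delta_combo.loc[gene].to_numpy(), expected, atol=1e-12)

    def test_knockout_of_zero_attribution_tf_barely_moves_prediction(self, tiny_pipeline):
        """Consistency between attribution and intervention on the fitted model."""
        from scregnet.attribution import shapley_attributions

        models = tiny_pipeline.trained.models
        deltas, attrs = [], []
        for gi, (gene, model) in enumerate(models.items()):
            attr = shapley_attributions(
                model.spec, model.params, model.training_features, n_perm=50, seed=gi
            )
            for k, tf in enumerate(model.spec.tf_ids):
                d = in_silico_knockout({gene: model}, tf).loc[gene].abs().mean()
                attrs.append(attr.gamma[k])
                deltas.append(d)
        attrs, deltas = np.asarray(attrs), np.asarray(deltas)
        # TFs with (near-)zero attribution produce (near-)zero interventions
        small = attrs < 1e-6
        if small.any():
            assert deltas[small].max() < 1e-4
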