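"""TF importance machinery and the TFB/CRP/TRP potential formulas."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scregnet.context import (
    binding_potential,
    celltype_specific_res,
    cis_potential,
    motif_enrichment,
    permutation_zscore,
    tf_importance,
    trans_potential,
)
from scregnet.types import AccessibilityMatrix


class TestSpecificRes:
    def _matrix(self, values, types):
        cols = [f"c{i}" for i in range(values.shape[1])]
        acc = AccessibilityMatrix(values, [f"r{i}" for i in range(values.shape[0])], cols)
        return acc, dict(zip(cols, types))

    def test_exclusive_re_top_ranked(self):
        values = np.array([[5.0, 5.0, 0.0, 0.0], [1.0, 1.0, 1.0, 1.0]])
        acc, types = self._matrix(values, ["A", "A", "B", "B"])
        assert celltype_specific_res(acc, types, "A", n_top=1) == ["r0"]

    def test_uniform_accessibility_ties_break_by_re_id(self):
        values = np.ones((3, 4))
        acc, types = self._matrix(values, ["A", "A", "B", "B"])
        assert celltype_specific_res(acc, types, "A", n_top=3) == ["r0", "r1", "r2"]

    def test_three_re_hand_ranking(self):
        # specificity scores for A: r0: 4-1=3, r1: 2-5=-3, r2: 3-3=0
        values = np.array([[4.0, 1.0], [2.0, 5.0], [3.0, 3.0]])
        acc, types = self._matrix(values, ["A", "B"])
        assert celltype_specific_res(acc, types, "A", n_top=3) == ["r0", "r2", "r1"]

    def test_single_type_rejected(self):
        acc, types = self._matrix(np.ones((2, 2)), ["A", "A"])
        with pytest.raises(ValueError, match="2 cell types"):
            celltype_specific_res(acc, types, "A")


class TestMotifEnrichment:
    def test_exclusive_motif_near_zero_p(self):
        re_ids = [f"r{i}" for i in range(40)]
        sites = np.zeros((1, 40), dtype=bool)
        sites[0, :10] = True
        p = motif_enrichment(sites, ["m"], re_ids, re_ids[:10])
        assert p["m"] < 1e-6

    def test_proportional_sites_not_enriched(self):
        re_ids = [f"r{i}" for i in range(40)]
        sites = np.zeros((1, 40), dtype=bool)
        sites[0, ::2] = True  # half in, half out
        p = motif_enrichment(sites, ["m"], re_ids, re_ids[:20])
        assert p["m"] > 0.3

    def test_hand_checked_hypergeometric_tail(self):
        # universe 75, motif carriers 15, specific 30, carriers in specific 10
        re_ids = [f"r{i}" for i in range(75)]
        sites = np.zeros((1, 75), dtype=bool)
        sites[0, :10] = True
        sites[0, 30:35] = True
        p = motif_enrichment(sites, ["m"], re_ids, re_ids[:30])
        assert p["m"] == pytest.approx(stats.hypergeom.sf(9, 75, 15, 30), abs=1e-12)

    def test_motif_without_sites_gets_p_one(self):
        p = motif_enrichment(np.zeros((1, 5), dtype=bool), ["m"], list("abcde"), ["a"])
        assert p["m"] == 1.0


class TestPermutationZscore:
    def test_independent_pairs_calibrated(self):
        rng = np.random.default_rng(0)
        tf = rng.standard_normal(120)
        acc = rng.standard_normal((40, 120))
        z = permutation_zscore(tf, acc, n_perm=300, seed=1)
        assert np.mean(np.abs(z) < 3) > 0.95

    def test_coupled_pair_strong_z(self):
        rng = np.random.default_rng(1)
        tf = rng.standard_normal(100)
        acc = tf[None, :] + 0.05 * rng.standard_normal((1, 100))
        z = permutation_zscore(tf, acc, n_perm=300, seed=2)
        assert z[0] > 5

    def test_constant_vector_gives_zero(self):
        tf = np.ones(50)
        acc = np.random.default_rng(2).random((3, 50))
        assert np.all(permutation_zscore(tf, acc, n_perm=100, seed=0) == 0.0)


class TestTfImportance:
    def _inputs(self):
        z = pd.DataFrame(
            [[1.0, 3.0, 2.0], [4.0, 0.0, -1.0]],
            index=["tfA", "tfB"],
            columns=["r1", "r2", "r3"],
        )
        sites = np.array([[True, True, False], [False, True, True]])
        return z, sites

    def test_no_enriched_motif_gives_zero(self):
        z, sites = self._inputs()
        p = pd.Series({"m1": 0.5, "m2": 0.9})
        s = tf_importance(z, p, sites, ["m1", "m2"], ["r1", "r2", "r3"],
                          [("tfA", "m1"), ("tfB", "m2")])
        assert s["tfA"] == 0.0 and s["tfB"] == 0.0

    def test_single_enriched_motif_equals_coactivity(self):
        z, sites = self._inputs()
        p = pd.Series({"m1": 0.01, "m2": 0.9})
        s = tf_importance(z, p, sites, ["m1", "m2"], ["r1", "r2", "r3"],
                          [("tfA", "m1")])
        assert s["tfA"] == pytest.approx((1.0 + 3.0) / 2)

    def test_two_enriched_motifs_average(self):
        z, sites = self._inputs()
        p = pd.Series({"m1": 0.01, "m2": 0.001})
        s = tf_importance(z, p, sites, ["m1", "m2"], ["r1", "r2", "r3"],
                          [("tfA", "m1"), ("tfA", "m2")])
        z_m1 = (1.0 + 3.0) / 2  # REs r1, r2
        z_m2 = (3.0 + 2.0) / 2  # REs r2, r3
        assert s["tfA"] == pytest.approx((z_m1 + z_m2) / 2)


class TestPotentialFormulas:
    def test_tfb_zero_importance_exponent(self):
        out = binding_potential(
            C=np.array([[0.37]]), s=np.array([0.0]),
            tf_expr_mean=np.array([2.0]), re_access_mean=np.array([3.0]),
            alpha=np.array([[0.25]]), B=np.array([[0.75]]),
        )
        assert out[0, 0] == pytest.approx(2.0 * 3.0 * 1.0, abs=1e-12)

    def test_tfb_zero_accessibility_zero(self):
        out = binding_potential(
            C=np.array([[0.9]]), s=np.array([1.0]),
            tf_expr_mean=np.array([2.0]), re_access_mean=np.array([0.0]),
            alpha=np.array([[0.5]]), B=np.array([[0.5]]),
        )
        assert out[0, 0] == 0.0

    def test_tfb_hand_value(self):
        out = binding_potential(
            C=np.array([[0.5]]), s=np.array([2.0]),
            tf_expr_mean=np.array([1.0]), re_access_mean=np.array([2.0]),
            alpha=np.array([[1.0]]), B=np.array([[2.0]]),
        )
        assert out[0, 0] == pytest.approx(0.25 * 1.0 * 2.0 * 3.0, abs=1e-12)  # 1.5

    def test_tfb_negative_affinity_sum_clamped(self):
        out = binding_potential(
            C=np.array([[1.0]]), s=np.array([1.0]),
            tf_expr_mean=np.array([1.0]), re_access_mean=np.array([1.0]),
            alpha=np.array([[-0.9]]), B=np.array([[0.2]]),
        )
        assert out[0, 0] == 0.0

    def test_crp_distance_decay_cases(self):
        assert cis_potential(1.0, 1.0, 1.0, np.array([0.0]))[0] == 1.0
        assert cis_potential(1.0, 1.0, 1.0, np.array([25_000.0]))[0] == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )
        assert cis_potential(0.5, 2.0, 3.0, np.array([50_000.0]))[0] == pytest.approx(
            3.0 * np.exp(-2.0), abs=1e-12
        )

    def test_crp_halves_every_d0_ln2(self):
        d0 = 25_000.0
        half = d0 * np.log(2)
        v = cis_potential(1.0, 1.0, 1.0, np.array([0.0, half, 2 * half]), d0=d0)
        assert v[1] == pytest.approx(v[0] / 2, abs=1e-12)
        assert v[2] == pytest.approx(v[0] / 4, abs=1e-12)

    def test_trp_empty_window_and_single_re(self):
        gamma = pd.DataFrame([[2.0, 3.0]], index=["tf"], columns=["g_empty", "g_one"])
        tfb = pd.DataFrame([[4.0]], index=["tf"], columns=["r1"])
        crp = {"g_empty": pd.Series(dtype=float), "g_one": pd.Series({"r1": 0.5})}
        trp = trans_potential(gamma, tfb, crp)
        assert trp.loc["tf", "g_empty"] == 0.0
        assert trp.loc["tf", "g_one"] == pytest.approx(3.0 * 4.0 * 0.5)

    def test_trp_matches_bruteforce_sum(self):
        rng = np.random.default_rng(3)
        tfs, res, genes = ["t1", "t2"], ["r1", "r2", "r3"], ["g1", "g2"]
        gamma = pd.DataFrame(rng.random((2, 2)), index=tfs, columns=genes)
        tfb = pd.DataFrame(rng.random((2, 3)), index=tfs, columns=res)
        crp = {
            "g1": pd.Series(rng.random(2), index=["r1", "r3"]),
            "g2": pd.Series(rng.random(3), index=res),
        }
        trp = trans_potential(gamma, tfb, crp)
        for t in tfs:
            for g in genes:
                brute = sum(gamma.loc[t, g] * tfb.loc[t, r] * crp[g][r] for r in crp[g].index)
                assert trp.loc[t, g] == pytest.approx(brute, abs=1e-12)


@pytest.fixture(scope="module")
def celltype_grn(tiny_pipeline):
    from scregnet.context import build_celltype_grn

    p = tiny_pipeline
    return build_celltype_grn(
        p.metacells, p.population, p.affinity, p.window,
        p.sites, p.network.motifs.motif_ids, p.network.motifs.tf_motif_pairs,
        "type1", n_top_res=10, n_perm=200, seed=0,
    )


class TestSmoothing:
    def test_identical_columns_unchanged(self):
        from scregnet.context import smooth_profiles

        values = np.tile(np.array([[1.0], [4.0]]), (1, 6))
        emb = np.zeros((6, 2))
        assert np.allclose(smooth_profiles(values, emb, k=3), values)

    def test_averaging_reduces_column_variance(self):
        from scregnet.context import smooth_profiles

        rng = np.random.default_rng(0)
        values = rng.random((5, 50))
        emb = rng.random((50, 3))
        smoothed = smooth_profiles(values, emb, k=10)
        assert smoothed.var(axis=1).sum() < values.var(axis=1).sum()


class TestContextIntegration:
    def test_potentials_nonnegative(self, celltype_grn):
        assert (celltype_grn.tfb.to_numpy() >= 0).all()
        for s in celltype_grn.crp.values():
            assert (s >= 0).all()
        assert (celltype_grn.trp.to_numpy() >= 0).all()

    def test_cell_equal_to_type_mean_reduces_to_type_grn(self, tiny_pipeline, celltype_grn):
        from scregnet.context import build_cell_level_grns
        from scregnet.types import AccessibilityMatrix, ExpressionMatrix

        p = tiny_pipeline
        cols = p.metacells.metacells_of_type("type1")
        e_mean = p.metacells.expression.subset_cols(cols).to_dense().mean(axis=1)
        o_mean = p.metacells.accessibility.subset_cols(cols).to_dense().mean(axis=1)
        expr = ExpressionMatrix(e_mean[:, None], p.metacells.expression.row_ids, ["cellX"])
        acc = AccessibilityMatrix(o_mean[:, None], p.metacells.accessibility.row_ids, ["cellX"])
        cell_grns = build_cell_level_grns(
            expr, acc, {"cellX": "type1"}, p.metacells, p.population, p.affinity,
            p.window, p.sites, p.network.motifs.motif_ids,
            p.network.motifs.tf_motif_pairs, n_top_res=10, n_perm=200, seed=0,
        )
        assert np.allclose(
            cell_grns["cellX"].trp.to_numpy(), celltype_grn.trp.to_numpy(), atol=1e-10
        )

    def test_cell_with_zero_accessibility_has_zero_potentials(self, tiny_pipeline):
        from scregnet.context import build_cell_level_grns
        from scregnet.types import AccessibilityMatrix, ExpressionMatrix

        p = tiny_pipeline
        n_genes = len(p.metacells.expression.row_ids)
        n_res = len(p.metacells.accessibility.row_ids)
        expr = ExpressionMatrix(
            np.ones((n_genes, 1)), p.metacells.expression.row_ids, ["dead"]
        )
        acc = AccessibilityMatrix(
            np.zeros((n_res, 1)), p.metacells.accessibility.row_ids, ["dead"]
        )
        grns = build_cell_level_grns(
            expr, acc, {"dead": "type1"}, p.metacells, p.population, p.affinity,
            p.window, p.sites, p.network.motifs.motif_ids,
            p.network.motifs.tf_motif_pairs, n_top_res=10, n_perm=100, seed=0,
        )
        assert grns["dead"].tfb.to_numpy().sum() == 0.0
        assert all(s.sum() == 0.0 for s in grns["dead"].crp.values() if not s.empty)

    def test_trp_rows_scale_with_tf_expression(self, tiny_pipeline):
        """Cell-level TRP is linear in that cell's TF expression row."""
        from scregnet.context import build_cell_level_grns
        from scregnet.types import AccessibilityMatrix, ExpressionMatrix

        p = tiny_pipeline
        tf0 = p.population.tf_ids[0]
        row = p.metacells.expression.row_ids.index(tf0)
        base = p.metacells.expression.to_dense()[:, :1].copy()
        doubled = base.copy()
        doubled[row] *= 2
        acc_col = p.metacells.accessibility.to_dense()[:, :1]
        expr = ExpressionMatrix(
            np.hstack([base, doubled]), p.metacells.expression.row_ids, ["a", "b"]
        )
        acc = AccessibilityMatrix(
            np.hstack([acc_col, acc_col]), p.metacells.accessibility.row_ids, ["a", "b"]
        )
        grns = build_cell_level_grns(
            expr, acc, {"a": "type1", "b": "type1"}, p.metacells, p.population,
            p.affinity, p.window, p.sites, p.network.motifs.motif_ids,
            p.network.motifs.tf_motif_pairs, n_top_res=10, n_perm=100, seed=0,
        )
        trp_a = grns["a"].trp.loc[tf0].to_numpy()
        trp_b = grns["b"].trp.loc[tf0].to_numpy()
        assert np.allclose(trp_b, 2 * trp_a, atol=1e-10)
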