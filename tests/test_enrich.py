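"""DE sets, hypergeometric enrichment, net-benefit matrix and scRNA-seq QC."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from anndata import AnnData
from scipy import sparse

from cardiophen import synth
from cardiophen.enrich import (
    cluster_zscores,
    de_sets,
    hypergeom_enrichment,
    net_benefit_matrix,
    qc_filter_cells,
)


def _table(folds: dict[str, float], base=100.0):
    """Two EV and two treated samples; each gene at a planted fold."""
    genes = list(folds)
    data = {
        "EV_1": [base] * len(genes),
        "EV_2": [base] * len(genes),
        "TX_1": [base * folds[g] for g in genes],
        "TX_2": [base * folds[g] for g in genes],
    }
    expr = pd.DataFrame(data, index=genes)
    cond = pd.Series(
        {"EV_1": "EV", "EV_2": "EV", "TX_1": "TX", "TX_2": "TX"}
    )
    return expr, cond


class TestDeSets:
    def test_threshold_arithmetic(self):
        """2x control is up; 1.4x is in neither set."""
        expr, cond = _table({"g2x": 2.0, "g14x": 1.4, "gflat": 1.0})
        up, down = de_sets(expr, cond, "TX", "EV")
        assert up == {"g2x"}
        assert down == set()

    def test_fold_exactly_threshold_excluded(self):
        """Strict inequality: a gene at exactly 1.5-fold is excluded."""
        # with pseudocount 1: (m+1)/(b+1) = 1.5 when m = 1.5 b + 0.5
        expr, cond = _table({"edge": 1.0})
        expr.loc["edge", ["TX_1", "TX_2"]] = 1.5 * 100.0 + 0.5
        up, down = de_sets(expr, cond, "TX", "EV")
        assert up == set() and down == set()

    def test_downregulation_on_ratio_scale(self):
        expr, cond = _table({"gdown": 0.4, "gmild": 0.8})
        up, down = de_sets(expr, cond, "TX", "EV")
        assert down == {"gdown"}
        assert up == set()

    def test_expression_floor_excludes_low_genes(self):
        sim = synth.gen_omics("bulk_expr", seed=5, n_below_floor=4)
        up, down = de_sets(sim.expr, sim.conditions, "MiMaC", "EV")
        assert not (up | down) & sim.below_floor_genes

    def test_planted_sets_recovered_exactly(self):
        sim = synth.gen_omics("bulk_expr", seed=6, n_up=12, n_down=7)
        up, down = de_sets(sim.expr, sim.conditions, "MiMaC", "EV")
        assert up == sim.up_genes
        assert down == sim.down_genes

    def test_missing_condition_rejected(self):
        expr, cond = _table({"g": 1.0})
        with pytest.raises(ValueError, match="no samples"):
            de_sets(expr, cond, "absent", "EV")


def _brute_force_hypergeom(n_universe, pathway, hits):
    """P(overlap >= observed) by enumerating every possible draw of |hits|."""
    universe = list(range(n_universe))
    pathway_set = set(range(pathway))
    observed = len(set(range(hits)) & pathway_set)  # hits are 0..hits-1
    total = ge = 0
    for draw in combinations(universe, hits):
        total += 1
        if len(set(draw) & pathway_set) >= observed:
            ge += 1
    return ge / total


class TestHypergeom:
    def test_worked_example_1_in_12(self):
        """|U|=10, |pathway|=5, |set|=3, overlap 3 -> C(5,3)/C(10,3) = 1/12."""
        u = {f"g{i}" for i in range(10)}
        pathway = {f"g{i}" for i in range(5)}
        hits = {"g0", "g1", "g2"}
        assert hypergeom_enrichment(hits, pathway, u) == pytest.approx(1 / 12)

    def test_pathway_equal_universe_gives_one(self):
        u = {f"g{i}" for i in range(8)}
        assert hypergeom_enrichment({"g0", "g3"}, u, u) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        ("n_u", "n_path", "n_hits"),
        [(10, 5, 3), (12, 4, 6), (9, 3, 3), (12, 6, 2), (7, 2, 5)],
    )
    def test_matches_exhaustive_enumeration(self, n_u, n_path, n_hits):
        """Upper-tail p equals brute-force enumeration on small universes."""
        u = {f"g{i}" for i in range(n_u)}
        pathway = {f"g{i}" for i in range(n_path)}
        hits = {f"g{i}" for i in range(n_hits)}
        expected = _brute_force_hypergeom(n_u, n_path, n_hits)
        assert hypergeom_enrichment(hits, pathway, u) == pytest.approx(expected)

    def test_zero_overlap_near_one(self):
        u = {f"g{i}" for i in range(12)}
        pathway = {f"g{i}" for i in range(4)}
        hits = {f"g{i}" for i in range(8, 12)}
        p = hypergeom_enrichment(hits, pathway, u)
        assert p == pytest.approx(1.0)

    def test_set_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            hypergeom_enrichment({"x"}, {"a"}, {"a", "b"})


class TestNetBenefit:
    def test_planted_up_enrichment_positive_and_matches_hand_value(self):
        sim = synth.gen_omics("bulk_expr", seed=7, n_up=10, n_down=10)
        pathway = set(list(sim.up_genes)[:6])  # inside the upregulated set
        res = net_benefit_matrix(
            sim.expr, sim.conditions, {"maturation": pathway}, control="EV"
        )
        cell = res.net_benefit.loc["maturation", "MiMaC"]
        assert cell > 0
        universe = set(sim.expr.index[sim.expr.sum(axis=1) > 1.0])
        p_up = hypergeom_enrichment(sim.up_genes, pathway, universe)
        p_down = hypergeom_enrichment(sim.down_genes, pathway, universe)
        assert cell == pytest.approx(np.log10(p_down) - np.log10(p_up))

    def test_control_column_is_zero(self):
        sim = synth.gen_omics("bulk_expr", seed=8)
        pathway = set(list(sim.up_genes)[:5])
        res = net_benefit_matrix(
            sim.expr, sim.conditions, {"p": pathway}, control="EV"
        )
        assert res.net_benefit.loc["p", "EV"] == 0.0

    def test_antisymmetric_under_up_down_exchange(self):
        """Swapping the up and down fold directions flips the sign."""
        up_first = synth.gen_omics("bulk_expr", seed=9, n_up=10, n_down=0)
        down_first = synth.gen_omics("bulk_expr", seed=9, n_up=0, n_down=10)
        # same planted gene ids become up in one table and down in the other
        pathway = set(list(up_first.up_genes)[:6])
        assert pathway == set(list(down_first.down_genes)[:6])
        a = net_benefit_matrix(
            up_first.expr, up_first.conditions, {"p": pathway}
        ).net_benefit.loc["p", "MiMaC"]
        b = net_benefit_matrix(
            down_first.expr, down_first.conditions, {"p": pathway}
        ).net_benefit.loc["p", "MiMaC"]
        assert a == pytest.approx(-b, rel=1e-9)

    def test_matrix_shape_is_pathways_by_conditions(self):
        sim = synth.gen_omics(
            "bulk_expr", seed=10,
            conditions={"EV": 2, "A": 2, "B": 2},
        )
        pathways = {f"p{i}": set(list(sim.up_genes)[i : i + 3]) for i in range(7)}
        res = net_benefit_matrix(sim.expr, sim.conditions, pathways)
        assert res.net_benefit.shape == (7, 3)
        assert list(res.net_benefit.index) == list(pathways)

    def test_serialization_round_trips(self, tmp_path):
        sim = synth.gen_omics("bulk_expr", seed=11)
        res = net_benefit_matrix(
            sim.expr, sim.conditions, {"p": set(list(sim.up_genes)[:4])}
        )
        path = tmp_path / "net_benefit.csv"
        res.net_benefit.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        pd.testing.assert_frame_equal(back, res.net_benefit)


class TestQCFilter:
    def test_boundary_cells_kept(self):
        """Equality passes: exactly 200 genes, 2000 UMIs, 40% mito."""
        n_genes = 250
        row = np.zeros(n_genes)
        row[:200] = 10  # 200 detected genes, 2000 UMIs total
        x = sparse.csr_matrix(np.vstack([row]))
        adata = AnnData(X=x)
        adata.var_names = [f"MT-{i}" if i < 80 else f"G{i}" for i in range(n_genes)]
        # mito = 80 genes x 10 = 800 of 2000 -> 40%
        filtered, counts = qc_filter_cells(adata)
        assert counts["total"] == 0
        assert filtered.n_obs == 1
        assert adata.obs["mito_fraction"].iloc[0] == pytest.approx(0.40)

    def test_planted_failures_removed_for_right_reasons(self):
        sim = synth.gen_omics("sc_counts", seed=12)
        filtered, counts = qc_filter_cells(sim.adata)
        assert counts["mito"] == len(sim.fail_mito)
        assert counts["genes"] == len(sim.fail_genes)
        assert counts["umis"] == len(sim.fail_umis)
        assert set(filtered.obs_names).isdisjoint(
            sim.fail_mito + sim.fail_genes + sim.fail_umis
        )

    def test_matches_row_wise_recomputation_oracle(self):
        """Filter decisions equal an independent per-row dense recomputation."""
        rng = np.random.default_rng(13)
        dense = rng.integers(0, 60, size=(40, 300)).astype(float)
        dense[rng.random(dense.shape) < 0.7] = 0
        adata = AnnData(X=sparse.csr_matrix(dense))
        adata.var_names = [f"MT-{i}" if i < 15 else f"G{i}" for i in range(300)]
        filtered, _ = qc_filter_cells(adata)
        kept_oracle = []
        for i in range(dense.shape[0]):
            row = dense[i]
            umis = row.sum()
            genes = (row > 0).sum()
            mito = row[:15].sum() / umis if umis > 0 else 0.0
            if mito <= 0.40 and genes >= 200 and umis >= 2000:
                kept_oracle.append(f"{i}")
        assert list(filtered.obs_names) == kept_oracle

    def test_no_mito_annotation_rejected(self):
        adata = AnnData(X=sparse.csr_matrix(np.ones((3, 5))))
        adata.var_names = [f"G{i}" for i in range(5)]
        with pytest.raises(ValueError, match="mitochondrial"):
            qc_filter_cells(adata)


class TestClusterZscores:
    def test_zscores_sum_to_zero_across_cells(self):
        rng = np.random.default_rng(14)
        expr = pd.DataFrame(
            rng.random((30, 4)), columns=list("ABCD"),
            index=[f"c{i}" for i in range(30)],
        )
        clusters = pd.Series(
            ["k0"] * 15 + ["k1"] * 15, index=expr.index
        )
        z, flagged = cluster_zscores(expr, clusters, ["A", "B"])
        # weighted by cluster sizes, the cluster means of z average to 0
        sizes = clusters.value_counts()[z.columns].to_numpy()
        np.testing.assert_allclose((z * sizes).sum(axis=1), 0.0, atol=1e-9)
        assert flagged == []

    def test_planted_marker_difference_has_positive_z_in_high_cluster(self):
        expr = pd.DataFrame(
            {"M": [2.0] * 10 + [1.0] * 10, "other": [1.0] * 20},
            index=[f"c{i}" for i in range(20)],
        )
        clusters = pd.Series(["hi"] * 10 + ["lo"] * 10, index=expr.index)
        z, flagged = cluster_zscores(expr, clusters, ["M", "other"])
        assert z.loc["M", "hi"] > 0 > z.loc["M", "lo"]
        assert flagged == ["other"]  # constant gene flagged, not NaN

    def test_constant_gene_row_is_zero_not_nan(self):
        expr = pd.DataFrame(
            {"flat": [3.0] * 6}, index=[f"c{i}" for i in range(6)]
        )
        clusters = pd.Series(["a"] * 3 + ["b"] * 3, index=expr.index)
        z, flagged = cluster_zscores(expr, clusters, ["flat"])
        assert flagged == ["flat"]
        assert not z.isna().any().any()
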