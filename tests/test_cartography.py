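"""Zg, Kpi, APCC, node roles, switch calls, biclustering."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from switchnet import ExpressionMatrix, SyntheticConfig, generate
from switchnet.cartography import (apcc, bicluster_switch, call_switch_genes,
                                   classify_nodes, clusterphobic_coefficient,
                                   linkage_to_newick, within_module_degree_z)

from conftest import (adj_to_nx, brute_clusterphobic, brute_pearson,
                      brute_within_module_degree_z, random_graph)


def series(d, name=None):
    return pd.Series(d, name=name)


class TestWithinModuleDegreeZ:
    def test_equal_within_degrees_all_zero(self):
        G = nx.cycle_graph(["a", "b", "c", "d"])
        zg = within_module_degree_z(G, series({n: 1 for n in G}))
        assert np.allclose(zg, 0.0)

    def test_hand_arithmetic_three_node_community(self):
        G = nx.Graph([("a", "b"), ("a", "c")])
        zg = within_module_degree_z(G, series({"a": 1, "b": 1, "c": 1}))
        sd = np.sqrt(((2 - 4 / 3) ** 2 + 2 * (1 - 4 / 3) ** 2) / 3)
        assert zg["a"] == pytest.approx((2 - 4 / 3) / sd)
        assert zg["b"] == pytest.approx((1 - 4 / 3) / sd)

    def test_cross_community_edges_do_not_count(self):
        G = nx.Graph([("a", "b"), ("a", "x"), ("a", "y")])
        comm = series({"a": 1, "b": 1, "x": 2, "y": 2})
        zg = within_module_degree_z(G, comm)
        # within community 1 both nodes have kappa=1 -> sd 0 -> 0
        assert zg["a"] == 0.0 and zg["b"] == 0.0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            adj = random_graph(rng, n=20, p=0.2)
            comm = {v: int(rng.integers(1, 4)) for v in adj}
            zg = within_module_degree_z(adj_to_nx(adj), series(comm))
            brute = brute_within_module_degree_z(adj, comm)
            for v in adj:
                assert zg[v] == pytest.approx(brute[v], abs=1e-12)


class TestClusterphobic:
    def test_all_internal_links(self):
        G = nx.complete_graph(["a", "b", "c"])
        kpi = clusterphobic_coefficient(G, series({n: 1 for n in G}))
        assert np.allclose(kpi, 0.0)

    def test_all_external_links(self):
        G = nx.star_graph(["hub", "x", "y", "z"])
        comm = series({"hub": 1, "x": 2, "y": 2, "z": 2})
        assert clusterphobic_coefficient(G, comm)["hub"] == pytest.approx(1.0)

    def test_two_internal_of_four(self):
        G = nx.Graph([("v", "a"), ("v", "b"), ("v", "x"), ("v", "y"),
                      ("a", "b")])
        comm = series({"v": 1, "a": 1, "b": 1, "x": 2, "y": 2})
        assert clusterphobic_coefficient(G, comm)["v"] == pytest.approx(0.75)

    def test_isolated_node_zero_by_convention(self):
        G = nx.Graph()
        G.add_nodes_from(["a", "b"])
        G.add_edge("a", "b")
        G.add_node("iso")
        kpi = clusterphobic_coefficient(G, series({"a": 1, "b": 1, "iso": 1}))
        assert kpi["iso"] == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            adj = random_graph(rng, n=18, p=0.25)
            comm = {v: int(rng.integers(1, 4)) for v in adj}
            kpi = clusterphobic_coefficient(adj_to_nx(adj), series(comm))
            brute = brute_clusterphobic(adj, comm)
            for v in adj:
                assert kpi[v] == pytest.approx(brute[v], abs=1e-12)


def test_kappa_conservation():
    """Summed within-community degree equals twice the intra-community edges."""
    rng = np.random.default_rng(2)
    for _ in range(10):
        adj = random_graph(rng, n=25, p=0.15)
        comm = {v: int(rng.integers(1, 5)) for v in adj}
        G = adj_to_nx(adj)
        kappa_sum = sum(sum(1 for w in G.neighbors(v) if comm[w] == comm[v])
                        for v in G)
        intra = sum(1 for u, v in G.edges if comm[u] == comm[v])
        assert kappa_sum == 2 * intra


class TestApcc:
    @staticmethod
    def expr_from(rows, genes):
        cols = [f"s{i}" for i in range(rows.shape[1])]
        half = rows.shape[1] // 2
        groups = pd.Series(["control"] * half + ["case"] * (rows.shape[1] - half),
                           index=cols)
        return ExpressionMatrix(pd.DataFrame(rows, index=genes, columns=cols), groups)

    def test_duplicate_neighbour_gives_one(self):
        rows = np.array([[1.0, 2.0, 4.0, 3.0], [1.0, 2.0, 4.0, 3.0]])
        expr = self.expr_from(rows, ["a", "b"])
        G = nx.Graph([("a", "b")])
        assert apcc(expr, G)["a"] == pytest.approx(1.0)

    def test_negated_neighbours_give_minus_one(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        expr = self.expr_from(np.vstack([base, -base, -base + 5]), ["a", "b", "c"])
        G = nx.Graph([("a", "b"), ("a", "c")])
        assert apcc(expr, G)["a"] == pytest.approx(-1.0)

    def test_isolated_node_is_nan(self):
        rows = np.random.default_rng(0).normal(size=(2, 6))
        expr = self.expr_from(rows, ["a", "b"])
        G = nx.Graph()
        G.add_nodes_from(["a", "b"])
        assert np.isnan(apcc(expr, G)["a"])

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(3)
        rows = rng.normal(size=(12, 10))
        genes = [f"g{i}" for i in range(12)]
        expr = self.expr_from(rows, genes)
        adj = random_graph(rng, n=12, p=0.3)
        mapping = dict(zip(sorted(adj), genes))
        G = nx.relabel_nodes(adj_to_nx(adj), mapping)
        values = apcc(expr, G)
        for g in genes:
            nbrs = list(G.neighbors(g))
            if not nbrs:
                continue
            expected = np.mean([brute_pearson(rows[genes.index(g)],
                                              rows[genes.index(nb)])
                                for nb in nbrs])
            assert values[g] == pytest.approx(expected, abs=1e-12)


class TestClassify:
    @staticmethod
    def classify_one(zg, kpi, a):
        cart = classify_nodes(series({"n": zg}), series({"n": kpi}),
                              series({"n": a}), series({"n": 1}))
        return cart.loc["n"]

    def test_negative_apcc_is_fight_club(self):
        assert self.classify_one(1.0, 0.5, -0.2)["hub_class"] == "fight_club"

    def test_apcc_zero_boundary_is_date(self):
        assert self.classify_one(1.0, 0.5, 0.0)["hub_class"] == "date"

    def test_high_positive_apcc_is_party(self):
        assert self.classify_one(1.0, 0.5, 0.7)["hub_class"] == "party"

    def test_low_zg_high_kpi_is_region_r4(self):
        assert self.classify_one(1.0, 0.9, -0.2)["region"] == "R4"

    @pytest.mark.parametrize("zg,kpi,region", [
        (0.0, 0.01, "R1"), (0.0, 0.3, "R2"), (0.0, 0.7, "R3"), (0.0, 0.85, "R4"),
        (3.0, 0.1, "R5"), (3.0, 0.5, "R6"), (3.0, 0.9, "R7"),
    ])
    def test_region_grid(self, zg, kpi, region):
        assert self.classify_one(zg, kpi, 0.1)["region"] == region

    def test_network_hub_flag_above_five(self):
        assert self.classify_one(5.5, 0.1, 0.9)["is_network_hub"]
        assert not self.classify_one(4.9, 0.1, 0.9)["is_network_hub"]


class TestSwitchCalls:
    @pytest.mark.parametrize("zg,kpi,a,expected", [
        (1.0, 0.9, -0.2, True),    # the canonical switch triple
        (2.5, 0.9, -0.2, False),   # zg boundary excluded (strict)
        (1.0, 0.8, -0.2, False),   # kpi boundary excluded
        (1.0, 0.9, 0.0, False),    # apcc boundary excluded
        (3.0, 0.9, -0.2, False),   # local hub
    ])
    def test_threshold_triple(self, zg, kpi, a, expected):
        cart = classify_nodes(series({"n": zg}), series({"n": kpi}),
                              series({"n": a}), series({"n": 1}))
        assert bool(cart.loc["n", "is_switch"]) is expected
        called = call_switch_genes(cart)
        assert (called == ["n"]) is expected

    def test_switch_subset_of_fight_club(self, strong_data):
        from switchnet import SwitchGeneModel

        expr, _ = strong_data
        res = SwitchGeneModel(expr, correlation_threshold=0.6).fit(seed=0)
        cart = res.cartography
        switch = set(cart.index[cart["is_switch"]])
        fight = set(cart.index[cart["hub_class"] == "fight_club"])
        negative = set(cart.index[cart["apcc"] < 0])
        assert switch <= fight <= negative

    def test_empty_switch_set_warns_not_raises(self, caplog):
        cart = classify_nodes(series({"n": 1.0}), series({"n": 0.1}),
                              series({"n": 0.5}), series({"n": 1}))
        with caplog.at_level("WARNING"):
            assert call_switch_genes(cart) == []
        assert any("no switch genes" in r.message for r in caplog.records)


class TestBicluster:
    @staticmethod
    def expr_from(rows, genes):
        return TestApcc.expr_from(np.asarray(rows, float), genes)

    def test_identical_rows_merge_first_at_zero_height(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=8)
        rows = [base, rng.normal(size=8), base, rng.normal(size=8)]
        expr = self.expr_from(rows, ["a", "b", "a2", "c"])
        bic = bicluster_switch(expr, ["a", "b", "a2", "c"])
        assert bic.linkage_rows[0, 2] == pytest.approx(0.0, abs=1e-12)
        merged = {int(bic.linkage_rows[0, 0]), int(bic.linkage_rows[0, 1])}
        assert merged == {0, 2}  # the duplicated profiles

    def test_row_order_permutation_invariant_heights(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(6, 10))
        genes = [f"g{i}" for i in range(6)]
        expr = self.expr_from(rows, genes)
        h1 = np.sort(bicluster_switch(expr, genes).linkage_rows[:, 2])
        perm = [genes[i] for i in rng.permutation(6)]
        h2 = np.sort(bicluster_switch(expr, perm).linkage_rows[:, 2])
        assert np.allclose(h1, h2)

    def test_two_planted_modules_form_clean_row_blocks(self):
        cfg = SyntheticConfig(n_modules=2, genes_per_module=5, n_switch=0,
                              n_noise_genes=0, noise_sd=0.0, loading=1.0, seed=6)
        expr, truth = generate(cfg)
        bic = bicluster_switch(expr, expr.gene_ids)
        labels = [truth.module_of[g] for g in bic.row_order]
        # contiguous blocks: exactly one transition along the leaf order
        transitions = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert transitions == 1

    def test_requires_two_rows(self, strong_data):
        expr, _ = strong_data
        with pytest.raises(ValueError):
            bicluster_switch(expr, [expr.gene_ids[0]])

    def test_orders_are_permutations(self, strong_data):
        expr, truth = strong_data
        bic = bicluster_switch(expr, sorted(truth.switch_genes))
        assert sorted(bic.row_order) == sorted(truth.switch_genes)
        assert sorted(bic.col_order) == sorted(expr.sample_ids)
        assert bic.matrix.shape == (len(truth.switch_genes), len(expr.sample_ids))


def test_linkage_to_newick_contains_all_labels():
    rng = np.random.default_rng(7)
    from scipy.cluster.hierarchy import linkage

    Z = linkage(rng.normal(size=(5, 4)), method="average")
    text = linkage_to_newick(Z, ["a", "b", "c", "d", "e"])
    assert text.endswith(";") and text.count("(") == text.count(")")
    for label in "abcde":
        assert label in text
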