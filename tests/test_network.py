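import numpy as np
import pandas as pd
import networkx as nx
import pytest

from oracles import best_modularity_partition, spearman_brute_force_p
from oxynet import network as netmod
from oxynet.errors import DataError


class TestWaterMasses:
    def test_constant_salinity_single_window(self):
        s = pd.Series([38.0] * 10, index=[f"W{i}" for i in range(10)])
        windows = netmod.detect_water_masses(s, 0.15)
        assert len(windows) == 1 and len(windows[0]) == 10

    def test_zero_tolerance_noisy_series(self):
        rng = np.random.default_rng(0)
        s = pd.Series(38 + rng.uniform(0.01, 0.2, size=20).cumsum())
        assert netmod.detect_water_masses(s, 0.0) == []

    def test_missing_weeks_break_runs(self):
        s = pd.Series([38.0, 38.0, 38.0, np.nan, 38.0, 38.0, 38.0, 38.0])
        windows = netmod.detect_water_masses(s, 0.1)
        assert [len(w) for w in windows] == [3, 4]

    def test_empty_series_rejected(self):
        with pytest.raises(DataError):
            netmod.detect_water_masses(pd.Series(dtype=float), 0.1)


class TestSpearman:
    def test_identical_series_rho_one(self):
        r = np.arange(1.0, 8.0)
        rho, p = netmod.spearman_exact_p(r, r)
        assert rho == pytest.approx(1.0)

    def test_exact_p_equals_brute_force(self):
        rng = np.random.default_rng(1)
        for n in (5, 6):
            for _ in range(3):
                x, y = rng.normal(size=n), rng.normal(size=n)
                rx = pd.Series(x).rank().to_numpy()
                ry = pd.Series(y).rank().to_numpy()
                rho, p = netmod.spearman_exact_p(rx, ry)
                rho_o, p_o = spearman_brute_force_p(x, y)
                assert rho == pytest.approx(rho_o, abs=1e-12)
                assert p == pytest.approx(p_o, abs=1e-12)

    def test_three_week_perfect_correlation_p_one_third(self):
        rho, p = netmod.spearman_exact_p(np.array([1.0, 2, 3]), np.array([1.0, 2, 3]))
        assert rho == 1.0 and p == pytest.approx(1 / 3)

    def test_edges_respect_threshold_and_flags(self):
        rng = np.random.default_rng(2)
        weeks = [f"W{i}" for i in range(3)]
        ab = pd.DataFrame(rng.uniform(1, 9, size=(4, 3)),
                          index=list("abcd"), columns=weeks)
        ab.loc["b"] = ab.loc["a"] * 2          # rho = +1
        ab.loc["c"] = 10 - ab.loc["a"]         # rho = -1
        ab.loc["d"] = [5.0, 5.0, 5.0]          # constant -> skipped
        w = netmod.WaterMassWindow("P1", weeks, 38.0, 0.05)
        edges = netmod.spearman_edges(ab, w, p_method="t")
        pairs = {e.taxa for e in edges}
        assert ("a", "b") in pairs and ("a", "c") in pairs
        assert all(e.low_support for e in edges)  # n = 3 < 5
        assert all(abs(e.rho) >= 0.7 and e.p < 0.05 for e in edges)
        assert not any("d" in e.taxa for e in edges)
        # the exact test can never certify an edge from a 3-week window
        assert netmod.spearman_edges(ab, w, p_method="exact") == []


def edge(a, b, rho=0.9, period="P1", p=0.01):
    return netmod.EdgeRecord((min(a, b), max(a, b)), rho, p,
                             1 if rho > 0 else -1, [period], 7)


class TestBuildNetwork:
    def test_no_edges_all_isolated(self):
        net = netmod.build_network([], ["a", "b", "c"])
        assert net.graph.number_of_edges() == 0
        assert (net.degree_table()["degree"] == 0).all()

    def test_triangle_degree_bookkeeping(self):
        net = netmod.build_network([edge("a", "b"), edge("b", "c"), edge("a", "c", rho=-0.8)], list("abc"))
        table = net.degree_table()
        assert (table["degree"] == 2).all()
        assert table["degree"].sum() == 2 * net.graph.number_of_edges()
        assert table.loc["a", "negative_degree"] == 1
        assert (table["positive_degree"] + table["negative_degree"]).equals(table["degree"])

    def test_duplicate_pair_merges_keeping_strongest(self):
        e1, e2 = edge("a", "b", rho=0.8, period="P1"), edge("a", "b", rho=1.0, period="P2")
        net = netmod.build_network([e1, e2], ["a", "b"])
        assert net.graph.number_of_edges() == 1
        rec = net.edges[0]
        assert rec.rho == pytest.approx(1.0)  # strongest period wins
        assert rec.periods == ["P1", "P2"]  # annotations will span both

    def test_self_edge_rejected(self):
        with pytest.raises(DataError, match="self-edge"):
            netmod.build_network([edge("a", "a")], ["a"])


class TestModules:
    def clique_network(self, sizes):
        edges, taxa = [], []
        start = 0
        for size in sizes:
            names = [f"n{start + i}" for i in range(size)]
            taxa.extend(names)
            for i in range(size):
                for j in range(i + 1, size):
                    edges.append(edge(names[i], names[j]))
            start += size
        return netmod.build_network(edges, taxa)

    def test_two_disjoint_cliques(self):
        net = netmod.find_modules(self.clique_network([5, 5]), seed=0)
        labels = set(net.modules.values())
        assert len(labels) == 2
        # closed form for two equal disconnected cliques: Q = 1/2
        assert net.modularity_q == pytest.approx(0.5)

    def test_single_clique_one_module(self):
        net = netmod.find_modules(self.clique_network([6]), seed=0)
        assert len(set(net.modules.values())) == 1

    def test_matches_exhaustive_search_on_small_graphs(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            g = nx.gnp_random_graph(6, 0.5, seed=int(rng.integers(1e6)))
            if g.number_of_edges() == 0:
                continue
            taxa = [f"t{i}" for i in g.nodes]
            edges = [edge(f"t{u}", f"t{v}") for u, v in g.edges]
            net = netmod.find_modules(netmod.build_network(edges, taxa), seed=0)
            pos = nx.relabel_nodes(g, {i: f"t{i}" for i in g.nodes})
            pos.remove_nodes_from(list(nx.isolates(pos)))
            q_star, _ = best_modularity_partition(pos)
            assert net.modularity_q == pytest.approx(q_star, abs=1e-9)

    def test_no_positive_edges_degenerate(self):
        net = netmod.find_modules(
            netmod.build_network([edge("a", "b", rho=-0.9)], ["a", "b"]), seed=0
        )
        assert net.modularity_q == 0.0
        assert all(m is None for m in net.modules.values())


class TestAnnotation:
    def make_profile(self, weeks, values):
        frame = pd.DataFrame(
            {c: values for c in netmod.CLASS_COLUMNS}, index=weeks, dtype=float
        )
        return frame

    def test_window_mean(self):
        w = netmod.WaterMassWindow("P1", ["W1", "W2", "W3"], 38.0, 0.05)
        prof = self.make_profile(["W1", "W2", "W3"], [10.0, 20.0, 30.0])
        e = edge("a", "b")
        netmod.annotate_edges([e], prof, [w])
        assert e.annotations["EPA-derived"] == pytest.approx(20.0)

    def test_two_period_edge_averages_periods(self):
        w1 = netmod.WaterMassWindow("P1", ["W1"], 38.0, 0.05)
        w2 = netmod.WaterMassWindow("P2", ["W2"], 38.0, 0.05)
        prof = self.make_profile(["W1", "W2"], [10.0, 30.0])
        e = netmod.EdgeRecord(("a", "b"), 0.9, 0.01, 1, ["P1", "P2"], 7)
        netmod.annotate_edges([e], prof, [w1, w2])
        assert e.annotations["HTrA-derived"] == pytest.approx(20.0)

    def test_missing_period_values_flagged(self):
        w = netmod.WaterMassWindow("P1", ["W1"], 38.0, 0.05)
        prof = self.make_profile(["W1"], [np.nan])
        e = edge("a", "b")
        netmod.annotate_edges([e], prof, [w])
        assert np.isnan(e.annotations["EPA-derived"])

    def test_unknown_period_rejected(self):
        e = edge("a", "b", period="P9")
        with pytest.raises(DataError, match="P9"):
            netmod.annotate_edges([e], self.make_profile(["W1"], [1.0]), [])


def planted_module_network(seed, n_per_clique=7, ratio=10.0):
    """Two cliques; module-1 edges carry ~10x higher HTrA annotation."""
    rng = np.random.default_rng(seed)
    edges, taxa = [], []
    for c, base in enumerate([1.0, ratio]):
        names = [f"m{c}_{i}" for i in range(n_per_clique)]
        taxa.extend(names)
        for i in range(n_per_clique):
            for j in range(i + 1, n_per_clique):
                e = edge(names[i], names[j])
                e.annotations = {
                    col: float(base * rng.lognormal(0, 0.2)) for col in netmod.CLASS_COLUMNS
                }
                edges.append(e)
    net = netmod.build_network(edges, taxa)
    return netmod.find_modules(net, seed=0)


class TestNullTests:
    def test_identical_annotations_give_null_result(self):
        net = planted_module_network(0, ratio=1.0)
        for e in net.edges:
            e.annotations = {c: 5.0 for c in netmod.CLASS_COLUMNS}
        res = netmod.null_module_test(net, "HTrA-derived", 200, seed=1)
        assert all(r.t_stat == 0.0 and r.p == 1.0 for r in res)

    def test_reshuffling_conserves_annotation_multiset(self):
        net = planted_module_network(1)
        pooled = netmod.pooled_null_samples(net, "HTrA-derived", reshuffles=50, seed=2)
        observed = np.sort(
            np.concatenate([
                [e.annotations["HTrA-derived"] for e in net.edges
                 if net.modules[e.taxa[0]] == net.modules[e.taxa[1]]]
            ])
        )
        modules = sorted(pooled)
        for k in range(50):
            shuffled = np.sort(np.concatenate([pooled[m][k] for m in modules]))
            np.testing.assert_array_equal(shuffled, observed)

    def test_planted_enrichment_detected(self):
        # a 10x enrichment of one module shifts both modules away from the
        # pooled null, so any module's two-tailed deviation is the signal
        hits = 0
        for seed in range(20):
            net = planted_module_network(seed)
            res = netmod.null_module_test(net, "HTrA-derived", 500, seed=seed)
            if min(r.p for r in res) < 0.01:
                hits += 1
        assert hits >= 19

    def test_pooled_variance_df_convention(self):
        """Equal variances at n1 = n2 = 130 intra-module edges give df = 258."""
        rng = np.random.default_rng(7)
        edges, taxa = [], []
        for c in range(2):
            # sparse ring-with-chords so each module holds exactly 130 edges
            names = [f"c{c}_{i}" for i in range(130)]
            taxa.extend(names)
            for i in range(130):
                e = edge(names[i], names[(i + 1) % 130])
                e.annotations = {col: float(rng.normal(10, 1)) for col in netmod.CLASS_COLUMNS}
                edges.append(e)
        net = netmod.build_network(edges, taxa)
        net.modules = {t: 0 if t.startswith("c0") else 1 for t in taxa}
        res = netmod.null_module_test(net, "EPA-derived", 200, seed=3)
        same_var = [r for r in res if r.equal_variance and r.n_observed == 130]
        assert same_var and all(r.df == 258 for r in same_var)

    def test_audit_rule_on_pipeline_network(self, dataset, profile):
        windows = netmod.detect_water_masses(dataset.environment["salinity"], 0.15)
        edges = []
        for w in windows:
            edges.extend(netmod.spearman_edges(dataset.abundance, w))
        net = netmod.build_network(edges, list(dataset.abundance.index))
        assert netmod.audit_edges(net)
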