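"""Co-activity network construction, topology metrics, and comparisons."""
import numpy as np
import pandas as pd
import pytest

import gillnet as g
from gillnet.datatypes import GillnetError
from gillnet.network import build_network, node_metrics, spearman_matrix

from _oracles import oracle_graph_metrics, oracle_spearman


def _site_table(rows, features, samples):
    return g.FeatureTable(pd.DataFrame(rows, index=features, columns=samples))


class TestSpearmanMatrix:
    def test_monotone_pairs(self):
        t = _site_table(
            [[1, 2, 3, 4, 5], [2, 4, 6, 8, 10], [10, 8, 6, 4, 2]],
            ["up1", "up2", "down"], [f"s{i}" for i in range(5)])
        rho, p = spearman_matrix(t)
        assert rho.loc["up1", "up2"] == pytest.approx(1.0)
        assert rho.loc["up1", "down"] == pytest.approx(-1.0)

    def test_tied_pair_matches_average_rank_formula(self):
        x = [1.0, 2.0, 2.0, 4.0, 5.0, 6.0]
        y = [3.0, 1.0, 4.0, 4.0, 6.0, 5.0]
        t = _site_table([x, y], ["x", "y"], [f"s{i}" for i in range(6)])
        rho, _ = spearman_matrix(t)
        assert rho.loc["x", "y"] == pytest.approx(oracle_spearman(x, y),
                                                  abs=1e-12)

    def test_constant_genus_excluded_with_warning(self):
        t = _site_table([[1, 1, 1, 1], [1, 2, 3, 4], [4, 3, 2, 1]],
                        ["flat", "a", "b"], [f"s{i}" for i in range(4)])
        with pytest.warns(UserWarning, match="constant"):
            rho, _ = spearman_matrix(t)
        assert "flat" not in rho.index

    def test_too_few_samples_rejected(self):
        t = _site_table([[1, 2, 3], [3, 2, 1]], ["a", "b"],
                        ["s1", "s2", "s3"])
        with pytest.raises(GillnetError, match="4 samples"):
            spearman_matrix(t)


class TestBuildNetwork:
    @staticmethod
    def _matrices(entries, ids):
        rho = pd.DataFrame(np.eye(len(ids)), index=ids, columns=ids)
        p = pd.DataFrame(np.zeros((len(ids), len(ids))), index=ids,
                         columns=ids)
        p.values[:] = 1.0
        np.fill_diagonal(p.values, 0.0)
        for a, b, r, pv in entries:
            rho.loc[a, b] = rho.loc[b, a] = r
            p.loc[a, b] = p.loc[b, a] = pv
        return rho, p

    def test_threshold_and_fdr_boundaries(self):
        ids = list("abcd")
        rho, p = self._matrices(
            [("a", "b", 0.39, 1e-6),    # below threshold: no edge
             ("a", "c", 0.50, 1e-6),    # kept, positive
             ("b", "c", -0.45, 0.9)],   # p too large: no edge
            ids)
        net = build_network(rho, p, threshold=0.4, alpha=0.05)
        edges = {tuple(sorted(e)) for e in net.graph.edges}
        assert edges == {("a", "c")}
        assert net.graph.edges["a", "c"]["sign"] == 1
        # isolated nodes are retained
        assert set(net.graph.nodes) == set(ids)

    def test_negative_edge_sign_recorded(self):
        ids = list("abc")
        rho, p = self._matrices([("a", "b", -0.8, 1e-8)], ids)
        net = build_network(rho, p)
        assert net.graph.edges["a", "b"]["sign"] == -1
        pos, neg = net.edge_sign_counts()
        assert (pos, neg) == (0, 1)

    def test_construction_invariant_to_genus_order(self, rng):
        n = 8
        ids = [f"g{i}" for i in range(n)]
        base = rng.uniform(-0.9, 0.9, size=(n, n))
        base = (base + base.T) / 2
        np.fill_diagonal(base, 1.0)
        pm = rng.uniform(0, 0.1, size=(n, n))
        pm = (pm + pm.T) / 2
        np.fill_diagonal(pm, 0.0)
        rho = pd.DataFrame(base, index=ids, columns=ids)
        p = pd.DataFrame(pm, index=ids, columns=ids)
        net1 = build_network(rho, p)
        perm = list(np.random.default_rng(1).permutation(ids))
        net2 = build_network(rho.loc[perm, perm], p.loc[perm, perm])
        assert ({tuple(sorted(e)) for e in net1.graph.edges}
                == {tuple(sorted(e)) for e in net2.graph.edges})


class TestNodeMetrics:
    def test_star_graph_by_hand(self):
        ids = ["center", "l1", "l2", "l3", "l4"]
        rho, p = TestBuildNetwork._matrices(
            [("center", leaf, 0.9, 1e-9) for leaf in ids[1:]], ids)
        net = build_network(rho, p)
        m = node_metrics(net)
        assert m.loc["center", "DG"] == 4
        assert m.loc["l1", "DG"] == 1
        assert m.loc["center", "NC"] == pytest.approx(1.0)
        assert m.loc["l1", "NC"] == pytest.approx(4.0)

    def test_path_graph_closeness(self):
        ids = ["e1", "mid", "e2"]
        rho, p = TestBuildNetwork._matrices(
            [("e1", "mid", 0.9, 1e-9), ("mid", "e2", 0.9, 1e-9)], ids)
        m = node_metrics(build_network(rho, p))
        assert m.loc["mid", "CC"] == pytest.approx(1.0)
        assert m.loc["e1", "CC"] == pytest.approx(1 / 1.5)

    def test_isolated_node_conventions(self):
        ids = list("abc")
        rho, p = TestBuildNetwork._matrices([("a", "b", 0.9, 1e-9)], ids)
        m = node_metrics(build_network(rho, p))
        assert m.loc["c", "DG"] == 0
        assert np.isnan(m.loc["c", "NC"])
        assert m.loc["c", "CC"] == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_oracle_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 15))
        ids = [f"n{i}" for i in range(n)]
        edges = [(ids[i], ids[j]) for i in range(n) for j in range(i + 1, n)
                 if rng.random() < 0.25]
        rho, p = TestBuildNetwork._matrices(
            [(a, b, 0.9, 1e-9) for a, b in edges], ids)
        m = node_metrics(build_network(rho, p))
        expected = oracle_graph_metrics(edges, ids)
        for node in ids:
            assert m.loc[node, "DG"] == expected[node]["DG"]
            if np.isnan(expected[node]["NC"]):
                assert np.isnan(m.loc[node, "NC"])
            else:
                assert m.loc[node, "NC"] == pytest.approx(expected[node]["NC"])
            assert m.loc[node, "CC"] == pytest.approx(expected[node]["CC"])


class TestCompareAndExport:
    @staticmethod
    def _net(edges, ids, site):
        rho, p = TestBuildNetwork._matrices(
            [(a, b, r, 1e-9) for a, b, r in edges], ids)
        return build_network(rho, p, site=site)

    def test_isomorphic_networks_compare_null(self):
        ids = [f"n{i}" for i in range(6)]
        edges = [("n0", "n1", 0.9), ("n1", "n2", 0.9), ("n3", "n4", -0.5)]
        nets = {"siteA": self._net(edges, ids, "siteA"),
                "siteB": self._net(edges, ids, "siteB")}
        tests, summary = g.compare_networks(nets)
        for res in tests.values():
            assert res.p_value == pytest.approx(1.0)
        assert summary.loc["siteA", "positive_edges"] == 2
        assert summary.loc["siteA", "negative_edges"] == 1
        assert (summary["positive_edges"] + summary["negative_edges"]
                == summary["n_edges"]).all()

    def test_dense_vs_sparse_detected(self):
        rng = np.random.default_rng(3)
        ids = [f"n{i}" for i in range(16)]
        dense = [(ids[i], ids[j], 0.8) for i in range(16)
                 for j in range(i + 1, 16) if rng.random() < 0.5]
        sparse = [("n0", "n1", 0.8), ("n2", "n3", 0.8)]
        nets = {"dense": self._net(dense, ids, "dense"),
                "sparse": self._net(sparse, ids, "sparse")}
        tests, summary = g.compare_networks(nets)
        assert summary.loc["dense", "median_DG"] > \
            summary.loc["sparse", "median_DG"]
        assert tests["DG"].p_value < 0.05

    def test_edge_list_round_trip(self, tmp_path):
        ids = list("abcd")
        net = self._net([("a", "b", 0.7), ("c", "d", -0.6)], ids, "s")
        path = tmp_path / "edges.tsv"
        g.export_network(net, path, "edgelist")
        from gillnet.network import read_edge_list
        back = read_edge_list(path)
        assert ({tuple(sorted(e)) for e in back.graph.edges}
                == {("a", "b"), ("c", "d")})
        assert back.graph.edges["c", "d"]["sign"] == -1

    def test_graphml_reimports_with_attributes(self, tmp_path):
        import networkx as nx
        ids = list("abc")
        rho, p = TestBuildNetwork._matrices([("a", "b", 0.7, 1e-9)], ids)
        net = build_network(rho, p, activity={"a": 0.5, "b": 0.3, "c": 0.2},
                            phylum={"a": "P1", "b": "P2", "c": "P1"})
        path = tmp_path / "net.graphml"
        g.export_network(net, path, "graphml")
        back = nx.read_graphml(path)
        assert back.nodes["a"]["phylum"] == "P1"
        assert back.nodes["a"]["DG"] == 1.0
        assert back.edges["a", "b"]["rho"] == pytest.approx(0.7)

    def test_empty_network_exports_header_only(self, tmp_path):
        ids = list("ab")
        net = self._net([], ids, "s")
        path = tmp_path / "empty.tsv"
        g.export_network(net, path, "edgelist")
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 1 and lines[0].startswith("node_a")

    def test_unknown_format_rejected(self, tmp_path):
        net = self._net([], list("ab"), "s")
        with pytest.raises(ValueError, match="format"):
            g.export_network(net, tmp_path / "x", "gexf")


class TestPlantedRecovery:
    def test_planted_modules_recovered(self):
        precs, recs = [], []
        for seed in range(5):
            ds = g.simulate_communities(g.network_recovery_config(seed))
            genus = g.aggregate_by_rank(
                g.to_relative_activity(ds.table), ds.taxonomy, "genus")
            rho, p = spearman_matrix(genus)
            net = build_network(rho, p)
            found = {(min(a, b), max(a, b)): d["sign"]
                     for a, b, d in net.graph.edges(data=True)}
            true = {(a, b): s for a, b, s in ds.truth.true_edge_set("site1")}
            tp = sum(1 for e, s in found.items() if true.get(e) == s)
            precs.append(tp / max(len(found), 1))
            recs.append(tp / len(true))
        assert np.mean(precs) >= 0.85
        assert np.mean(recs) >= 0.85

    def test_null_data_yields_almost_no_edges(self):
        total = 0
        n_rep = 10
        for seed in range(n_rep):
            cfg = g.SimulationConfig(
                seed=3000 + seed, n_sites=1, samples_per_site=[30],
                n_taxa=40, taxa_per_genus=1,
                depth_lognormal=(float(np.log(30000.0)), 0.3))
            ds = g.simulate_communities(cfg)
            genus = g.aggregate_by_rank(
                g.to_relative_activity(ds.table), ds.taxonomy, "genus")
            rho, p = spearman_matrix(genus)
            total += build_network(rho, p).n_edges
        n_pairs = 40 * 39 // 2
        assert total / n_rep <= 2 * 0.05 * n_pairs
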