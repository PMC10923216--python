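"""UniFrac, ordination, and permutation inference."""
import numpy as np
import pandas as pd
import pytest

import gillnet as g
from gillnet.datatypes import DataValidationError, GillnetError

from _oracles import (oracle_ols_r2, oracle_permanova_exact_p,
                      oracle_permanova_f, oracle_unifrac_pair)


def _random_dataset(seed, n_leaves=8, n_samples=4):
    rng = np.random.default_rng(seed)
    tree, _ = g.simulate_tree(n_leaves, seed=seed)
    counts = rng.integers(0, 60, size=(n_leaves, n_samples)).astype(float)
    counts[rng.integers(0, n_leaves), :] += 1  # keep all samples non-empty
    table = g.FeatureTable(pd.DataFrame(
        counts, index=tree.leaf_names,
        columns=[f"s{i}" for i in range(n_samples)]))
    return table, tree


class TestUnifrac:
    def test_identical_samples_are_at_distance_zero(self):
        table, tree = _random_dataset(0, n_samples=1)
        dup = g.FeatureTable(pd.DataFrame(
            np.hstack([table.values, table.values]),
            index=table.feature_ids, columns=["a", "b"]))
        for weighted in (False, True):
            dm = g.unifrac(dup, tree, weighted=weighted)
            assert dm[("a", "b")] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_samples_on_star_tree_are_at_distance_one(self):
        tree = g.PhyloTree.from_newick("(a:1,b:1,c:1,d:1);")
        table = g.FeatureTable(pd.DataFrame(
            [[5, 0], [3, 0], [0, 2], [0, 7]],
            index=["a", "b", "c", "d"], columns=["s1", "s2"]))
        assert g.unifrac(table, tree, weighted=False)[("s1", "s2")] == \
            pytest.approx(1.0)
        assert g.unifrac(table, tree, weighted=True,
                         normalized=True)[("s1", "s2")] == pytest.approx(1.0)

    def test_weighted_raw_on_star_tree_is_l1_distance(self):
        tree = g.PhyloTree.from_newick("(a:1,b:1,c:1);")
        table = g.FeatureTable(pd.DataFrame(
            [[6, 1], [3, 1], [1, 2]], index=["a", "b", "c"],
            columns=["s1", "s2"]))
        p = table.values / table.values.sum(axis=0)
        expected = np.abs(p[:, 0] - p[:, 1]).sum()
        assert g.unifrac(table, tree, weighted=True,
                         normalized=False)[("s1", "s2")] == \
            pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("weighted,normalized", [
        (False, True), (True, True), (True, False)])
    def test_matches_branch_enumeration_oracle(self, weighted, normalized):
        for seed in range(6):
            table, tree = _random_dataset(seed)
            dm = g.unifrac(table, tree, weighted=weighted,
                           normalized=normalized)
            counts = {s: table.data[s].to_dict() for s in table.sample_ids}
            for i, a in enumerate(table.sample_ids):
                for b in table.sample_ids[i + 1:]:
                    expected = oracle_unifrac_pair(
                        counts[a], counts[b], tree, weighted, normalized)
                    assert dm[(a, b)] == pytest.approx(expected, abs=1e-12)

    def test_matches_scikit_bio(self):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        from skbio import TreeNode
        import io as _io
        table, tree = _random_dataset(5, n_leaves=10, n_samples=5)
        sk_tree = TreeNode.read(_io.StringIO(tree.to_newick()))
        for metric in ("unweighted_unifrac", "weighted_unifrac"):
            sk = skbio_diversity.beta_diversity(
                metric, table.values.T.astype(int), ids=table.sample_ids,
                taxa=table.feature_ids, tree=sk_tree)
            ours = g.unifrac(table, tree,
                             weighted=not metric.startswith("unweighted"),
                             normalized=False)
            np.testing.assert_allclose(
                ours.values, sk.data, atol=1e-10)

    def test_empty_sample_and_missing_feature_rejected(self):
        table, tree = _random_dataset(1)
        empty = g.FeatureTable(pd.DataFrame(
            np.hstack([table.values, np.zeros((table.n_features, 1))]),
            index=table.feature_ids, columns=[*table.sample_ids, "void"]))
        with pytest.raises(DataValidationError, match="empty"):
            g.unifrac(empty, tree, weighted=True)
        extra = g.FeatureTable(pd.DataFrame(
            np.vstack([table.values, np.ones((1, table.n_samples))]),
            index=[*table.feature_ids, "ghost"], columns=table.sample_ids))
        with pytest.raises(DataValidationError, match="ghost"):
            g.unifrac(extra, tree, weighted=False)


class TestPcoa:
    def test_collinear_points_give_one_axis(self):
        d = np.array([[0, 1, 3], [1, 0, 2], [3, 2, 0]], dtype=float)
        res = g.pcoa(g.DistanceMatrix(d, ["a", "b", "c"]))
        pos = res.eigenvalues[res.eigenvalues > 1e-9]
        assert len(pos) == 1
        coords = res.coordinates.to_numpy()
        for i, j, expect in [(0, 1, 1.0), (0, 2, 3.0), (1, 2, 2.0)]:
            got = np.linalg.norm(coords[i] - coords[j])
            assert got == pytest.approx(expect, abs=1e-9)

    def test_euclidean_input_is_reconstructed_exactly(self, rng):
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = g.pcoa(g.DistanceMatrix(d, list("abcdef")))
        coords = res.coordinates.to_numpy()
        rebuilt = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.testing.assert_allclose(rebuilt, d, atol=1e-9)
        assert np.all(np.diff(res.eigenvalues) <= 1e-9)  # descending

    def test_coincident_points_give_zero_solution(self):
        d = np.zeros((4, 4))
        with pytest.raises(GillnetError):
            g.pcoa(g.DistanceMatrix(d[:2, :2], ["a", "b"]))
        res = g.pcoa(g.DistanceMatrix(d, list("abcd")))
        assert res.coordinates.shape[1] == 0
        assert np.all(np.abs(res.eigenvalues) < 1e-9)

    def test_matches_scikit_bio_eigenvalues(self, rng):
        skbio_ord = pytest.importorskip("skbio.stats.ordination")
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = g.DistanceMatrix(d, [f"s{i}" for i in range(7)])
        ours = g.pcoa(dm)
        from skbio import DistanceMatrix as SkDM
        theirs = skbio_ord.pcoa(SkDM(d, ids=dm.ids))
        np.testing.assert_allclose(
            ours.eigenvalues[:4], theirs.eigvals.to_numpy()[:4], atol=1e-8)


class TestPermanova:
    @staticmethod
    def _toy():
        rng = np.random.default_rng(8)
        pts = np.vstack([rng.normal(0, 1, size=(3, 2)),
                         rng.normal(2.5, 1, size=(3, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(6)]
        labels = pd.Series(["a"] * 3 + ["b"] * 3, index=ids)
        return g.DistanceMatrix(d, ids), labels, d

    def test_statistic_matches_pair_loop_oracle(self):
        dm, labels, d = self._toy()
        res = g.permanova(dm, labels, n_permutations=99, seed=0)
        assert res.pseudo_F == pytest.approx(
            oracle_permanova_f(d, list(labels)), rel=1e-12)
        assert 0.0 <= res.R2 <= 1.0

    def test_p_close_to_exact_enumeration(self):
        dm, labels, d = self._toy()
        exact = oracle_permanova_exact_p(d, list(labels))
        res = g.permanova(dm, labels, n_permutations=9999, seed=11)
        se = np.sqrt(exact * (1 - exact) / 9999)
        assert abs(res.p_value - exact) <= 3 * se + 1e-4

    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(4, 2))
        pts = np.vstack([pts, pts])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(8)]
        labels = pd.Series(["a"] * 4 + ["b"] * 4, index=ids)
        res = g.permanova(g.DistanceMatrix(d, ids), labels,
                          n_permutations=999, seed=2)
        assert res.pseudo_F == pytest.approx(0.0, abs=1e-9)
        assert res.p_value > 0.9

    def test_invariant_to_sample_order(self):
        dm, labels, _ = self._toy()
        res1 = g.permanova(dm, labels, n_permutations=499, seed=7)
        shuffled = dm.reorder(["s3", "s5", "s0", "s1", "s4", "s2"])
        res2 = g.permanova(shuffled, labels, n_permutations=499, seed=7)
        assert res1.p_value == res2.p_value
        assert res1.pseudo_F == pytest.approx(res2.pseudo_F)

    def test_statistic_matches_scikit_bio(self):
        sk = pytest.importorskip("skbio.stats.distance")
        dm, labels, d = self._toy()
        theirs = sk.permanova(sk.DistanceMatrix(d, ids=dm.ids),
                              grouping=list(labels), permutations=0)
        res = g.permanova(dm, labels, n_permutations=9, seed=0)
        assert res.pseudo_F == pytest.approx(theirs["test statistic"],
                                             rel=1e-10)

    def test_singleton_group_rejected(self):
        dm, labels, _ = self._toy()
        labels = labels.copy()
        labels.iloc[0] = "c"
        with pytest.raises(GillnetError, match="singleton"):
            g.permanova(dm, labels, n_permutations=9)


class TestPairwiseAndBetadisper:
    def test_three_identical_groups_all_null(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(4, 2))
        pts = np.vstack([pts, pts, pts])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(12)]
        labels = pd.Series(["a"] * 4 + ["b"] * 4 + ["c"] * 4, index=ids)
        out = g.pairwise_permanova(g.DistanceMatrix(d, ids), labels,
                                   n_permutations=199, seed=1)
        assert (out["p_adjusted"] > 0.5).all()
        assert (out["p_adjusted"] >= out["p_value"] - 1e-12).all()

    def test_displaced_group_reaches_floor_after_bh(self):
        rng = np.random.default_rng(6)
        pts = np.vstack([rng.normal(0, 0.5, size=(8, 2)),
                         rng.normal(0, 0.5, size=(8, 2)),
                         rng.normal(6, 0.5, size=(8, 2))])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(24)]
        labels = pd.Series(["a"] * 8 + ["b"] * 8 + ["c"] * 8, index=ids)
        out = g.pairwise_permanova(g.DistanceMatrix(d, ids), labels,
                                   n_permutations=999, seed=3)
        hit = out[(out.group_a != "b") | (out.group_b != "b")]
        c_rows = out[(out.group_a == "c") | (out.group_b == "c")]
        # both comparisons involving the displaced group reach the BH floor
        assert (c_rows["p_adjusted"] <= 0.0015).all()
        assert hit is not None

    def test_translated_copies_have_equal_dispersion(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(6, 2))
        shifted = pts + np.array([5.0, -3.0])
        allpts = np.vstack([pts, shifted])
        d = np.linalg.norm(allpts[:, None] - allpts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(12)]
        labels = pd.Series(["a"] * 6 + ["b"] * 6, index=ids)
        res = g.betadisper(g.DistanceMatrix(d, ids), labels,
                           n_permutations=499, seed=4)
        assert res.statistic == pytest.approx(0.0, abs=1e-18)
        assert res.p_value > 0.9

    def test_scaled_group_is_detected(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(12, 2))
        spread = pts * 4.0 + 10.0
        allpts = np.vstack([pts, spread])
        d = np.linalg.norm(allpts[:, None] - allpts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(24)]
        labels = pd.Series(["a"] * 12 + ["b"] * 12, index=ids)
        res = g.betadisper(g.DistanceMatrix(d, ids), labels,
                           n_permutations=999, seed=5)
        assert res.p_value <= 0.002
        assert res.group_means["b"] > res.group_means["a"]

    def test_centroid_distances_match_direct_euclidean(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(10, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"s{i}" for i in range(10)]
        labels = pd.Series(["a"] * 5 + ["b"] * 5, index=ids)
        res = g.betadisper(g.DistanceMatrix(d, ids), labels,
                           n_permutations=9, seed=0)
        # ids are re-sorted internally; compare by label
        for grp, idx in (("a", range(5)), ("b", range(5, 10))):
            centroid = pts[list(idx)].mean(axis=0)
            for i in idx:
                expected = np.linalg.norm(pts[i] - centroid)
                assert res.distances[f"s{i}"] == pytest.approx(expected,
                                                               abs=1e-9)


class TestNmds:
    def test_planar_configuration_is_recovered_with_tiny_stress(self):
        rng = np.random.default_rng(12)
        pts = rng.uniform(-1, 1, size=(4, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        res = g.nmds(g.DistanceMatrix(d, list("abcd")), k=2, n_starts=10,
                     seed=3)
        assert res.stress < 1e-4

    def test_stress_invariant_to_rotation_and_reflection(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(7, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = g.DistanceMatrix(d, [f"s{i}" for i in range(7)])
        res = g.nmds(dm, seed=1, n_starts=5)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        X = res.coordinates.to_numpy() @ rot
        X[:, 0] *= -1  # reflection
        dvec = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        orig = res.coordinates.to_numpy()
        dorig = np.linalg.norm(orig[:, None] - orig[None, :], axis=-1)
        np.testing.assert_allclose(dvec, dorig, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_majorization_trace_is_monotone(self, seed):
        rng = np.random.default_rng(seed)
        n = 10
        d = rng.uniform(0.5, 2.0, size=(n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0.0)
        res = g.nmds(g.DistanceMatrix(d, [f"s{i}" for i in range(n)]),
                     seed=seed, n_starts=3)
        assert np.all(np.diff(res.trace) <= 1e-10)

    def test_too_few_samples_rejected(self):
        d = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=float)
        with pytest.raises(GillnetError):
            g.nmds(g.DistanceMatrix(d, list("abc")), k=2)


class TestEnvfit:
    @staticmethod
    def _coords(rng, n=30):
        return pd.DataFrame(rng.normal(size=(n, 2)),
                            index=[f"s{i}" for i in range(n)],
                            columns=["A1", "A2"])

    def test_variable_equal_to_axis_is_perfectly_fit(self, rng):
        coords = self._coords(rng)
        env = pd.DataFrame({"ax1": coords["A1"]})
        out = g.envfit(coords, env, n_permutations=99, seed=0)
        assert out["r2"].iloc[0] == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(
            np.abs(out[["A1", "A2"]].iloc[0].to_numpy()), [1.0, 0.0],
            atol=1e-9)

    def test_r2_matches_normal_equations_oracle(self, rng):
        coords = self._coords(rng)
        y = (0.8 * coords["A1"] - 0.4 * coords["A2"]
             + rng.normal(scale=0.6, size=len(coords)))
        out = g.envfit(coords, pd.DataFrame({"y": y}), n_permutations=49,
                       seed=1)
        expected = oracle_ols_r2(coords.to_numpy(), y.to_numpy())
        assert out["r2"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_constant_variable_flagged_and_bonferroni_applied(self, rng):
        coords = self._coords(rng)
        env = pd.DataFrame({
            "flat": np.ones(len(coords)),
            "v1": coords["A1"] + rng.normal(scale=0.5, size=len(coords)),
            "v2": rng.normal(size=len(coords)),
        }, index=coords.index)
        with pytest.warns(UserWarning, match="constant"):
            out = g.envfit(coords, env, n_permutations=199, seed=2)
        assert np.isnan(out.loc[out.variable == "flat", "r2"].iloc[0])
        adj = out.loc[out.variable == "v1"]
        assert adj["p_adjusted"].iloc[0] == pytest.approx(
            min(1.0, adj["p_value"].iloc[0] * 2))
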