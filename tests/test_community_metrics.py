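"""Diversity metrics, ordination, and permutation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import cdist

from concreta.community_metrics import (DistanceMatrix, betadisper,
                                        distance_matrix, faith_pd,
                                        generalized_unifrac, mantel,
                                        occurrence_entropy, pcoa, permanova,
                                        rarefy, replicate_similarity_test,
                                        shannon)
from concreta.simulate import generate_tree
from concreta.tables_io import AsvTable


def _table(counts, meta=None):
    counts = pd.DataFrame(counts)
    return AsvTable(counts, meta)


@pytest.fixture()
def star_tables():
    """Two samples on disjoint taxon sets + a star tree (no shared
    internal branches, so disjoint samples are maximally distant)."""
    from skbio import TreeNode
    counts = pd.DataFrame(
        [[5, 5, 0, 0], [0, 0, 3, 7]],
        index=["s1", "s2"], columns=["a", "b", "c", "d"])
    # rooted star: binary root with zero-length internal edges
    tree = TreeNode.read(["((a:0.2,b:0.3):0.0,(c:0.1,d:0.4):0.0)root;"])
    return AsvTable(counts), tree


class TestRarefy:
    def test_sample_at_depth_unchanged(self):
        t = _table({"a": [600, 700], "b": [400, 500]})
        out, dropped = rarefy(t, depth=1000, seed=0)
        assert out.counts.loc[out.sample_ids[0]].sum() == 1000
        assert out.counts.iloc[0].tolist() == [600, 400]

    def test_under_depth_samples_dropped_and_listed(self):
        t = _table(pd.DataFrame({"a": [100, 5000]}, index=["lo", "hi"]))
        out, dropped = rarefy(t, depth=1000, seed=0)
        assert dropped == ["lo"] and out.sample_ids == ["hi"]

    def test_seed_reproducibility(self):
        t = _table({"a": [5000], "b": [3000]})
        o1, _ = rarefy(t, 1000, seed=42)
        o2, _ = rarefy(t, 1000, seed=42)
        assert o1.counts.equals(o2.counts)

    def test_expectation_matches_hypergeometric(self):
        t = _table({"a": [3000], "b": [1000]})
        draws = np.array([rarefy(t, 1000, seed=k)[0].counts.iloc[0, 0]
                          for k in range(200)])
        expected = 1000 * 3000 / 4000
        se = np.sqrt(1000 * 0.75 * 0.25)  # binomial envelope
        assert abs(draws.mean() - expected) < 4 * se / np.sqrt(200)


class TestAlpha:
    def test_shannon_of_four_equal_taxa_is_two_bits(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(2.0)

    def test_single_taxon_zero_entropy(self):
        assert shannon([7]) == pytest.approx(0.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            shannon([0, 0])

    def test_faith_pd_full_sample_is_total_branch_length(self):
        tree = generate_tree(16, seed=3)
        ids = [t.name for t in tree.tips()]
        total = sum(n.length for n in tree.traverse() if n.length)
        assert faith_pd(np.ones(16), tree, ids) == pytest.approx(total)

    def test_faith_pd_single_taxon_is_root_path(self):
        tree = generate_tree(8, seed=4)
        ids = [t.name for t in tree.tips()]
        leaf = next(tree.tips())
        path = 0.0
        node = leaf
        while node.parent is not None:
            path += node.length
            node = node.parent
        counts = np.zeros(8)
        counts[ids.index(leaf.name)] = 3
        assert faith_pd(counts, tree, ids) == pytest.approx(path)


class TestDistances:
    def test_identical_samples_give_zero_for_every_metric(self):
        counts = pd.DataFrame([[4, 6, 2]] * 2, index=["s1", "s2"],
                              columns=["a", "b", "c"])
        tree = generate_tree(3, seed=1, leaf_names=["a", "b", "c"])
        t = AsvTable(counts)
        for metric in ("bray_curtis", "jaccard", "unweighted_unifrac",
                       "weighted_unifrac_raw", "weighted_unifrac_normalized",
                       "generalized_unifrac"):
            d = distance_matrix(t, metric, tree=tree)
            assert d.data[0, 1] == pytest.approx(0.0, abs=1e-12), metric

    def test_disjoint_samples_maximal_jaccard_and_unweighted(self, star_tables):
        t, tree = star_tables
        assert distance_matrix(t, "jaccard").data[0, 1] == pytest.approx(1.0)
        assert distance_matrix(
            t, "unweighted_unifrac", tree=tree).data[0, 1] == pytest.approx(1.0)

    def test_generalized_alpha_one_equals_weighted_normalized(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 60, size=(11, 12)),
                              columns=[f"a{i}" for i in range(12)])
        tree = generate_tree(12, seed=9,
                             leaf_names=[f"a{i}" for i in range(12)])
        t = AsvTable(counts)
        g1 = distance_matrix(t, "generalized_unifrac", tree=tree, alpha=1.0)
        wn = distance_matrix(t, "weighted_unifrac_normalized", tree=tree)
        assert np.abs(g1.data - wn.data).max() < 1e-12  # 55 pairs

    def test_missing_tree_rejected(self, star_tables):
        t, _ = star_tables
        with pytest.raises(ValueError, match="phylogeny"):
            distance_matrix(t, "generalized_unifrac")

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(rng.integers(0, 40, size=(6, 8)),
                              index=[f"s{i}" for i in range(6)])
        t = AsvTable(counts)
        d = distance_matrix(t, "bray_curtis")
        perm = [3, 1, 5, 0, 2, 4]
        t2 = t.select_samples([t.sample_ids[i] for i in perm])
        d2 = distance_matrix(t2, "bray_curtis")
        assert np.allclose(d2.data, d.data[np.ix_(perm, perm)])

    def test_generalized_monotone_in_shared_mass(self):
        # adding identical counts to both samples never increases d
        rng = np.random.default_rng(2)
        ids = [f"a{i}" for i in range(10)]
        tree = generate_tree(10, seed=11, leaf_names=ids)
        for _ in range(10):
            base = rng.integers(0, 30, size=(2, 10))
            add = rng.integers(0, 20, size=10)
            t1 = AsvTable(pd.DataFrame(base, columns=ids))
            t2 = AsvTable(pd.DataFrame(base + add, columns=ids))
            d1 = generalized_unifrac(t1, tree, 0.5).data[0, 1]
            d2 = generalized_unifrac(t2, tree, 0.5).data[0, 1]
            assert d2 <= d1 + 1e-12


class TestPcoa:
    def test_three_equidistant_points_two_equal_eigenvalues(self):
        d = DistanceMatrix("m", ["a", "b", "c"],
                           np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]],
                                    dtype=float))
        _, evals, _ = pcoa(d)
        assert evals[0] == pytest.approx(evals[1])
        assert evals[0] > 0

    def test_collinear_points_single_positive_eigenvalue(self):
        x = np.array([0.0, 1.0, 3.0, 7.0])[:, None]
        d = DistanceMatrix("m", list("abcd"), cdist(x, x))
        coords, evals, _ = pcoa(d)
        assert evals[0] > 1e-9
        assert np.all(np.abs(evals[1:]) < 1e-9)
        emb = cdist(coords.to_numpy(), coords.to_numpy())
        assert np.abs(emb - d.data).max() < 1e-9

    def test_euclidean_round_trip(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 4))
        d = DistanceMatrix("m", [f"s{i}" for i in range(9)], cdist(pts, pts))
        coords, _, _ = pcoa(d)
        emb = cdist(coords.to_numpy(), coords.to_numpy())
        assert np.abs(emb - d.data).max() < 1e-9

    def test_too_few_samples_rejected(self):
        d = DistanceMatrix("m", ["a", "b"], np.array([[0, 1], [1, 0.]]))
        with pytest.raises(ValueError):
            pcoa(d)


def _random_distance(rng, n):
    pts = rng.normal(size=(n, 3))
    return DistanceMatrix("m", [f"s{i}" for i in range(n)], cdist(pts, pts))


class TestPermanova:
    def test_single_term_sequential_equals_marginal(self):
        rng = np.random.default_rng(0)
        d = _random_distance(rng, 16)
        md = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8}, index=d.ids)
        seq = permanova(d, md, ["g"], "sequential", 99, seed=1)
        mar = permanova(d, md, ["g"], "marginal", 99, seed=1)
        assert np.allclose(seq.table[["R2", "F"]], mar.table[["R2", "F"]])
        assert seq.table.p.iloc[0] == mar.table.p.iloc[0]

    def test_matches_skbio_single_factor_pseudo_f(self):
        # independent reference implementation for one categorical term
        from skbio.stats.distance import permanova as skbio_permanova
        rng = np.random.default_rng(4)
        d = _random_distance(rng, 18)
        groups = ["a"] * 9 + ["b"] * 9
        md = pd.DataFrame({"g": groups}, index=d.ids)
        ours = permanova(d, md, ["g"], "sequential", 99, seed=1)
        ref = skbio_permanova(d.to_skbio(), grouping=groups, permutations=0)
        assert ours.table.F.iloc[0] == pytest.approx(ref["test statistic"],
                                                     rel=1e-10)

    def test_planted_separation_minimal_p(self):
        rng = np.random.default_rng(1)
        pts = np.vstack([rng.normal(0, 0.1, size=(10, 3)),
                         rng.normal(8, 0.1, size=(10, 3))])
        d = DistanceMatrix("m", [f"s{i}" for i in range(20)], cdist(pts, pts))
        md = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10}, index=d.ids)
        res = permanova(d, md, ["g"], "sequential", 199, seed=2)
        assert res.table.p.iloc[0] == pytest.approx(1.0 / 200)

    def test_sequential_r2_sums_to_one_with_residual(self):
        rng = np.random.default_rng(2)
        d = _random_distance(rng, 20)
        md = pd.DataFrame({
            "x": rng.normal(size=20), "y": rng.normal(size=20),
            "g": ["a", "b"] * 10}, index=d.ids)
        res = permanova(d, md, ["x", "y", "g"], "sequential", 49, seed=3)
        resid_r2 = 1 - res.table.R2.sum()
        assert res.table.R2.sum() + resid_r2 == pytest.approx(1.0, abs=1e-9)
        assert 0 < resid_r2 < 1

    def test_constant_term_rejected(self):
        rng = np.random.default_rng(3)
        d = _random_distance(rng, 10)
        md = pd.DataFrame({"c": np.ones(10)}, index=d.ids)
        with pytest.raises(ValueError, match="constant"):
            permanova(d, md, ["c"], "sequential", 9, seed=1)

    def test_aliased_term_reported(self):
        rng = np.random.default_rng(5)
        d = _random_distance(rng, 12)
        x = rng.normal(size=12)
        md = pd.DataFrame({"x": x, "x2": 2 * x}, index=d.ids)
        with pytest.raises(ValueError, match="aliased"):
            permanova(d, md, ["x", "x2"], "sequential", 9, seed=1)


class TestBetadisper:
    def test_zero_dispersion_group_detected(self):
        rng = np.random.default_rng(0)
        tight = np.tile(rng.normal(size=3), (8, 1))
        loose = rng.normal(0, 2, size=(8, 3))
        pts = np.vstack([tight, loose])
        d = DistanceMatrix("m", [f"s{i}" for i in range(16)], cdist(pts, pts))
        groups = ["tight"] * 8 + ["loose"] * 8
        _, f, p = betadisper(d, pd.Series(groups, index=d.ids), 199, seed=1)
        assert p < 0.05

    def test_identical_groups_f_near_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(8, 3))
        both = np.vstack([pts, pts + 5])  # same shape, shifted centroid
        d = DistanceMatrix("m", [f"s{i}" for i in range(16)], cdist(both, both))
        groups = ["a"] * 8 + ["b"] * 8
        _, f, p = betadisper(d, pd.Series(groups, index=d.ids), 99, seed=1)
        assert f == pytest.approx(0.0, abs=1e-9)

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(2)
        d = _random_distance(rng, 5)
        with pytest.raises(ValueError, match="singleton"):
            betadisper(d, pd.Series(["a"] * 4 + ["b"], index=d.ids))


class TestMantelAndSimilarity:
    def test_mantel_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        d = _random_distance(rng, 10)
        r, p = mantel(d, d, permutations=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_mantel_affine_invariance(self):
        rng = np.random.default_rng(1)
        d1 = _random_distance(rng, 10)
        d2 = DistanceMatrix("m", d1.ids, 0.3 + 2.0 * d1.data)
        np.fill_diagonal(d2.data, 0.0)
        r, _ = mantel(d1, d2, permutations=99, seed=1)
        assert r == pytest.approx(1.0)

    def test_replicate_similarity_separated(self):
        data = np.full((6, 6), 0.9)  # distances: within 0.1, between 0.9
        data[:3, :3] = 0.1
        data[3:, 3:] = 0.1
        np.fill_diagonal(data, 0.0)
        d = DistanceMatrix("m", [f"s{i}" for i in range(6)], data)
        groups = ["g1"] * 3 + ["g2"] * 3
        w, b, p = replicate_similarity_test(d, pd.Series(groups, index=d.ids))
        assert w == pytest.approx(0.9) and b == pytest.approx(0.1)
        assert p < 1e-6

    def test_replicate_similarity_null_is_not_significant(self):
        rng = np.random.default_rng(3)
        d = _random_distance(rng, 12)
        groups = pd.Series(["g1", "g2", "g3", "g4"] * 3, index=d.ids)
        _, _, p = replicate_similarity_test(d, groups)
        assert p > 0.01


class TestOccurrenceEntropy:
    def _table(self):
        counts = pd.DataFrame({
            "confined": [5, 3, 0, 0, 0, 0, 0, 0],
            "everywhere": [1, 1, 1, 1, 1, 1, 1, 1],
            "absent": [0] * 8},
            index=[f"s{i}" for i in range(8)])
        return AsvTable(counts)

    def test_confined_zero_entropy_and_uniform_two_bits(self):
        t = self._table()
        groups = ["g1", "g1", "g2", "g2", "g3", "g3", "g4", "g4"]
        rel, ent = occurrence_entropy(t, groups)
        assert ent["confined"] == pytest.approx(0.0)
        assert ent["everywhere"] == pytest.approx(2.0)
        assert np.isnan(ent["absent"])

    def test_three_group_manual_case(self):
        counts = pd.DataFrame({"a": [1, 1, 1, 0, 0, 1]},
                              index=[f"s{i}" for i in range(6)])
        groups = ["g1", "g1", "g2", "g2", "g3", "g3"]
        rel, ent = occurrence_entropy(AsvTable(counts), groups)
        # occurrence freqs: (1, 0.5, 0.5) -> normalized (0.5, 0.25, 0.25)
        assert rel.loc["a"].tolist() == pytest.approx([0.5, 0.25, 0.25])
        assert ent["a"] == pytest.approx(1.5)  # -sum p log2 p
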