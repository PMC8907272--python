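"""Jaccard distances, UPGMA trees, dendrogram cutting, ANOSIM."""

from itertools import combinations

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform
from scipy.stats import rankdata

from assemblage_dnci import (
    DissimilarityMatrix,
    IncidenceMatrix,
    anosim,
    assign_clusters,
    jaccard_matrix,
    upgma,
)
from assemblage_dnci.exceptions import ConfigurationError, ValidationError


def random_dissimilarity(n, seed):
    rng = np.random.default_rng(seed)
    cond = rng.uniform(0.05, 1.0, n * (n - 1) // 2)
    return DissimilarityMatrix(squareform(cond), [f"L{i}" for i in range(n)])


class TestJaccard:
    def test_hand_counted_values(self):
        values = np.array(
            [
                [1, 1, 1, 0],  # {A,B,C}
                [0, 1, 1, 1],  # {B,C,D}
                [1, 1, 1, 0],  # identical to row 0
                [0, 0, 0, 1],  # disjoint from row 0
            ],
            dtype=np.int8,
        )
        m = IncidenceMatrix(values, ["L1", "L2", "L3", "L4"], list("ABCD"))
        d = jaccard_matrix(m)
        assert d.values[0, 1] == pytest.approx(1 - 2 / 4)
        assert d.values[0, 2] == 0.0
        assert d.values[0, 3] == 1.0

    def test_all_zero_row_rejected(self):
        values = np.array([[1, 0], [0, 0]], dtype=np.int8)
        m = IncidenceMatrix(values, ["L1", "L2"], ["A", "B"])
        with pytest.raises(ValidationError):
            jaccard_matrix(m)


class TestUPGMA:
    def test_forced_merge_order(self):
        d = DissimilarityMatrix(
            np.array([[0, 0.1, 0.8], [0.1, 0, 0.8], [0.8, 0.8, 0]]),
            ["L1", "L2", "L3"],
        )
        tree = upgma(d)
        assert tree.linkage[0, :3].tolist() == [0, 1, 0.1]
        assert tree.linkage[1, 2] == pytest.approx(0.8)

    def test_equidistant_tie_broken_by_lowest_label_pair(self):
        d = DissimilarityMatrix(
            np.array([[0, 0.5, 0.5], [0.5, 0, 0.5], [0.5, 0.5, 0]]),
            ["L1", "L2", "L3"],
        )
        tree = upgma(d)
        assert tree.linkage[0, 0] == 0 and tree.linkage[0, 1] == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_scipy_average_linkage(self, seed):
        """Cophenetic distances agree with scipy's textbook implementation
        on random 6-level matrices (ties almost surely absent)."""
        d = random_dissimilarity(6, seed)
        mine = upgma(d).linkage
        ref = linkage(d.condensed(), method="average")
        assert np.allclose(cophenet(mine), cophenet(ref))

    @pytest.mark.parametrize("seed", range(4))
    def test_heights_are_monotone_nondecreasing(self, seed):
        tree = upgma(random_dissimilarity(8, seed))
        heights = tree.heights
        assert (np.diff(heights) >= -1e-12).all()

    def test_newick_export_parses_and_sums_heights(self):
        d = random_dissimilarity(5, 3)
        tree = upgma(d)
        nwk = tree.to_newick()
        assert nwk.endswith(";") and nwk.count("(") == 4
        for label in d.level_ids:
            assert label in nwk


def planted_two_blocks(within=0.1, between=0.9, size=4):
    n = 2 * size
    M = np.full((n, n), between)
    M[:size, :size] = within
    M[size:, size:] = within
    np.fill_diagonal(M, 0.0)
    return DissimilarityMatrix(M, [f"L{i}" for i in range(n)])


class TestAssignClusters:
    def test_planted_blocks_found_without_removals(self):
        d = planted_two_blocks()
        res = assign_clusters(upgma(d), d)
        assert res.k == 2 and not res.removed_levels
        members = res.cluster_members()
        assert sorted(map(sorted, members.values())) == [
            [f"L{i}" for i in range(4)],
            [f"L{i}" for i in range(4, 8)],
        ]

    def test_outlier_level_is_removed_as_singleton(self):
        d = planted_two_blocks().values
        n = d.shape[0] + 1
        M = np.full((n, n), 0.98)
        M[:-1, :-1] = d
        np.fill_diagonal(M, 0.0)
        dm = DissimilarityMatrix(M, [f"L{i}" for i in range(n)])
        res = assign_clusters(upgma(dm), dm)
        assert res.removed_levels == [f"L{n - 1}"]
        assert res.k == 2
        assert f"L{n - 1}" not in res.assignment

    def test_forced_k_near_n_keeps_at_most_one_cluster(self):
        d = planted_two_blocks(size=3)
        res = assign_clusters(upgma(d), d, k=d.n - 1)
        assert res.k <= 1

    def test_k_out_of_range_rejected(self):
        d = planted_two_blocks(size=3)
        with pytest.raises(ConfigurationError):
            assign_clusters(upgma(d), d, k=d.n)

    def test_partition_invariant_under_level_relabelling(self):
        d = planted_two_blocks()
        perm = np.array([3, 6, 0, 7, 1, 4, 2, 5])
        d2 = DissimilarityMatrix(
            d.values[np.ix_(perm, perm)], [d.level_ids[i] for i in perm]
        )
        res1 = assign_clusters(upgma(d), d)
        res2 = assign_clusters(upgma(d2), d2)
        parts1 = sorted(sorted(ms) for ms in res1.cluster_members().values())
        parts2 = sorted(sorted(ms) for ms in res2.cluster_members().values())
        assert parts1 == parts2


def exhaustive_anosim(values, sizes):
    """R statistic for every label arrangement with fixed group sizes."""
    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(values[iu, ju])
    denom = n * (n - 1) / 4.0
    rs = []
    for grp1 in combinations(range(n), sizes[0]):
        g = np.zeros(n, dtype=int)
        g[list(grp1)] = 1
        within = g[iu] == g[ju]
        rs.append((ranks[~within].mean() - ranks[within].mean()) / denom)
    return np.array(rs)


class TestANOSIM:
    def test_maximal_separation_gives_r_one(self):
        d = planted_two_blocks(within=0.1, between=0.9, size=3)
        assignment = {f"L{i}": 1 if i < 3 else 2 for i in range(6)}
        r, p = anosim(d, assignment, n_perm=99, rng=0)
        assert r == pytest.approx(1.0)

    def test_r_matches_exhaustive_enumeration(self):
        d = random_dissimilarity(6, 11)
        assignment = {f"L{i}": 1 if i < 3 else 2 for i in range(6)}
        r, p = anosim(d, assignment, n_perm=999, rng=1)
        rs = exhaustive_anosim(d.values, (3, 3))
        g = np.zeros(6, dtype=int)
        g[:3] = 1
        # direct recomputation of the observed R
        iu, ju = np.triu_indices(6, k=1)
        ranks = rankdata(d.values[iu, ju])
        within = (g[iu] == g[ju])
        r_direct = (ranks[~within].mean() - ranks[within].mean()) / (6 * 5 / 4)
        assert r == pytest.approx(r_direct, abs=1e-12)
        # permutation p close to the exhaustive tail probability
        p_exact = (rs >= r - 1e-12).mean()
        assert abs(p - p_exact) < 0.12

    def test_r_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import anosim as sk_anosim

        d = random_dissimilarity(8, 5)
        assignment = {f"L{i}": 1 if i < 4 else 2 for i in range(8)}
        r, _ = anosim(d, assignment, n_perm=99, rng=0)
        dm = skbio.DistanceMatrix(d.values, ids=d.level_ids)
        ref = sk_anosim(dm, grouping=[1, 1, 1, 1, 2, 2, 2, 2], permutations=99)
        assert r == pytest.approx(float(ref["test statistic"]), abs=1e-12)

    def test_rank_based_invariance_under_monotone_transform(self):
        d = random_dissimilarity(8, 7)
        assignment = {f"L{i}": 1 if i < 4 else 2 for i in range(8)}
        r1, p1 = anosim(d, assignment, n_perm=999, rng=5)
        d2 = DissimilarityMatrix(np.sqrt(d.values), d.level_ids)
        r2, p2 = anosim(d2, assignment, n_perm=999, rng=5)
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert p1 == p2

    def test_planted_partition_highly_significant(self):
        # blocks of 7 so the permutation floor (2/C(14,7)) sits below 1e-3
        d = planted_two_blocks(size=7)
        assignment = {f"L{i}": 1 if i < 7 else 2 for i in range(14)}
        r, p = anosim(d, assignment, n_perm=9999, rng=2)
        assert p <= 0.001

    def test_singleton_cluster_rejected(self):
        d = planted_two_blocks(size=3)
        assignment = {"L0": 1, "L1": 1, "L2": 2}
        with pytest.raises(ValidationError):
            anosim(d, {**assignment, "L3": 2, "L4": 2, "L5": 3}, n_perm=99)
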