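"""SIMPER decomposition, permutation nulls, E statistic and the DNCI."""

import numpy as np
import pytest

from assemblage_dnci import (
    IncidenceMatrix,
    dnci_multigroup,
    dnci_pair,
    e_distribution,
    e_statistic,
    permute,
    persimper_report,
    simper,
    simulate,
    SimulationConfig,
)
from assemblage_dnci.exceptions import (
    AnalysisNotPossibleError,
    ConfigurationError,
    UndefinedDNCIError,
    ValidationError,
)
from assemblage_dnci.persimper import SimperProfile, classify

from conftest import bruteforce_simper


def matrix_from(values, prefix="L"):
    values = np.asarray(values, dtype=np.int8)
    n, t = values.shape
    return IncidenceMatrix(
        values, [f"{prefix}{i}" for i in range(n)], [f"t{j}" for j in range(t)]
    )


class TestSimper:
    def test_fully_distinct_single_taxon_groups(self):
        m = matrix_from([[1, 0], [1, 0], [0, 1], [0, 1]])
        prof = simper(m, ["L0", "L1"], ["L2", "L3"])
        assert prof.oad == pytest.approx(1.0)
        assert prof.contributions == {"t0": pytest.approx(50.0), "t1": pytest.approx(50.0)}

    def test_identical_groups_return_empty_profile(self):
        m = matrix_from([[1, 1], [1, 1], [1, 1], [1, 1]])
        prof = simper(m, ["L0", "L1"], ["L2", "L3"])
        assert prof.oad == 0.0
        assert prof.contributions == {}
        assert prof.profile.size == 0

    def test_matches_bruteforce_pairwise_decomposition(self, toy_matrix):
        prof = simper(toy_matrix, ["L1", "L2"], ["L3", "L4"])
        oad, contribs = bruteforce_simper(toy_matrix.values, 2)
        percents = 100 * contribs / contribs.sum()
        assert prof.oad == pytest.approx(oad)
        for taxon, pct in zip(toy_matrix.taxon_ids, percents):
            assert prof.contributions[taxon] == pytest.approx(pct)
        assert sum(prof.contributions.values()) == pytest.approx(100.0, abs=1e-9)
        assert (np.diff(prof.profile) <= 1e-12).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        X = (rng.random((7, 9)) < 0.45).astype(np.int8)
        X[X.sum(axis=1) == 0, 0] = 1
        m = matrix_from(X)
        g1 = [f"L{i}" for i in range(3)]
        g2 = [f"L{i}" for i in range(3, 7)]
        prof = simper(m, g1, g2)
        keep = X.sum(axis=0) > 0
        oad, contribs = bruteforce_simper(X[:, keep], 3)
        percents = 100 * contribs / contribs.sum()
        got = np.array([prof.contributions[t] for t, k in zip(m.taxon_ids, keep) if k])
        assert prof.oad == pytest.approx(oad)
        assert np.allclose(got, percents)

    def test_overlapping_groups_rejected(self, toy_matrix):
        with pytest.raises(ValidationError):
            simper(toy_matrix, ["L1", "L2"], ["L2", "L3"])

    def test_empty_level_rejected(self):
        m = matrix_from([[1, 0], [0, 0], [0, 1], [1, 1]])
        with pytest.raises(ValidationError):
            simper(m, ["L0", "L1"], ["L2", "L3"])

    def test_distribution_cases_tagged(self):
        m = matrix_from(
            [
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [0, 1, 0, 1],
                [0, 1, 0, 0],
            ]
        )
        prof = simper(m, ["L0", "L1"], ["L2", "L3"])
        assert prof.cases["t0"] == "widespread-in-one"  # common above, absent below
        assert prof.cases["t1"] == "widespread-even"
        assert set(prof.cases.values()) <= {
            "widespread-in-one",
            "widespread-even",
            "rare-even",
            "rare-in-one",
        }


class TestPermutationSchemes:
    @pytest.mark.parametrize("scheme,fixed", [
        ("niche", "rows"),
        ("dispersal", "cols"),
        ("both", "both"),
    ])
    def test_margins_conserved_exactly(self, scheme, fixed):
        rng = np.random.default_rng(1)
        X = (rng.random((12, 18)) < 0.35).astype(np.int8)
        m = matrix_from(X)
        gen = np.random.default_rng(2)
        for _ in range(100):
            out = permute(m, scheme, gen).values
            if fixed in ("rows", "both"):
                assert np.array_equal(out.sum(axis=1), X.sum(axis=1))
            if fixed in ("cols", "both"):
                assert np.array_equal(out.sum(axis=0), X.sum(axis=0))

    def test_niche_scheme_leaves_full_row_unchanged(self):
        X = np.zeros((4, 5), dtype=np.int8)
        X[0] = 1  # full row: nothing to rearrange
        X[1, 0] = X[2, 1] = X[3, 2] = 1
        m = matrix_from(X)
        out = permute(m, "niche", np.random.default_rng(0)).values
        assert (out[0] == 1).all()

    def test_unknown_scheme_rejected(self, toy_matrix):
        with pytest.raises(ConfigurationError):
            permute(toy_matrix, "neutral", np.random.default_rng(0))

    def test_permute_preserves_labels_and_binary_domain(self, toy_matrix):
        out = permute(toy_matrix, "both", np.random.default_rng(3))
        assert out.level_ids == toy_matrix.level_ids
        assert out.taxon_ids == toy_matrix.taxon_ids
        assert set(np.unique(out.values)) <= {0, 1}


class TestEStatistic:
    def test_identical_profiles_hit_floor(self):
        assert e_statistic(np.array([60.0, 40.0]), np.array([60.0, 40.0])) == -12.0

    def test_direct_arithmetic_example(self):
        # (60,40) vs (50,50): 10^2 + 10^2 = 200
        e = e_statistic(np.array([60.0, 40.0]), np.array([50.0, 50.0]))
        assert e == pytest.approx(np.log10(200), abs=1e-12)

    def test_symmetric_in_arguments(self):
        a, b = np.array([70.0, 20.0, 10.0]), np.array([40.0, 40.0, 20.0])
        assert e_statistic(a, b) == e_statistic(b, a)

    def test_zero_padding_to_common_length(self):
        e = e_statistic(np.array([60.0, 40.0]), np.array([100.0]), length=3)
        assert e == pytest.approx(np.log10(40**2 + 40**2))

    def test_profile_longer_than_padding_rejected(self):
        with pytest.raises(ValidationError):
            e_statistic(np.array([60.0, 40.0]), np.array([100.0]), length=1)

    def test_e_distribution_shape_and_finiteness(self, block_matrix):
        g1 = [f"L{i}" for i in range(4)]
        g2 = [f"L{i}" for i in range(4, 8)]
        dist = e_distribution(block_matrix, g1, g2, "niche", n_perm=50, rng=0)
        assert dist.n_perm == 50 and len(dist.e_values) == 50
        assert np.isfinite(dist.e_values).all()


class TestDNCI:
    def test_unbalanced_bookkeeping(self):
        ds = simulate(SimulationConfig(regime="dispersal", seed=4))
        g = ds.groups
        res = dnci_pair(
            ds.matrix, g["1"], g["2"][:12], n_perm=50, n_subsamples=100, rng=9
        )
        assert len(res.per_subsample) == 100
        assert res.cluster_sizes == (12, 12)
        assert res.n_subsamples == 100
        assert res.classification == classify(res.ci_low, res.ci_high)

    def test_balanced_groups_skip_subsampling(self, block_matrix):
        g1 = [f"L{i}" for i in range(4)]
        g2 = [f"L{i}" for i in range(4, 8)]
        res = dnci_pair(block_matrix, g1, g2, n_perm=60, rng=1)
        assert res.n_subsamples == 0
        assert res.cluster_sizes == (4, 4)
        assert len(res.per_subsample) == 1
        assert res.ci_low <= res.dnci <= res.ci_high

    def test_identical_seed_reproduces_bitwise(self, block_matrix):
        g1 = [f"L{i}" for i in range(4)]
        g2 = [f"L{i}" for i in range(4, 8)]
        a = dnci_pair(block_matrix, g1, g2, n_perm=40, rng=7)
        b = dnci_pair(block_matrix, g1, g2, n_perm=40, rng=7)
        assert a.dnci == b.dnci and a.ci_low == b.ci_low
        assert np.array_equal(a.dnci_values, b.dnci_values)

    def test_taxon_order_invariance(self, block_matrix):
        g1 = [f"L{i}" for i in range(4)]
        g2 = [f"L{i}" for i in range(4, 8)]
        perm = np.random.default_rng(0).permutation(block_matrix.n_taxa)
        shuffled = IncidenceMatrix(
            block_matrix.values[:, perm],
            list(block_matrix.level_ids),
            [block_matrix.taxon_ids[j] for j in perm],
            dict(block_matrix.metadata),
        )
        a = dnci_pair(block_matrix, g1, g2, n_perm=40, rng=5)
        b = dnci_pair(shuffled, g1, g2, n_perm=40, rng=5)
        assert a.dnci == pytest.approx(b.dnci)

    def test_degenerate_identical_clusters_undefined(self):
        m = matrix_from([[1, 1], [1, 1], [1, 1], [1, 1]])
        with pytest.raises(UndefinedDNCIError):
            dnci_pair(m, ["L0", "L1"], ["L2", "L3"], n_perm=20, rng=0)

    def test_dispersal_regime_yields_negative_significant_index(self):
        ds = simulate(SimulationConfig(regime="dispersal", seed=1))
        g = ds.groups
        res = dnci_pair(ds.matrix, g["1"], g["2"], n_perm=200, rng=1)
        assert res.dnci < 0 and res.ci_high < 0
        assert res.classification == "dispersal"

    def test_dispersal_regime_scheme_asymmetry(self):
        """On a dispersal-assembled matrix the taxon-frequency-preserving
        null tracks the empirical profile more closely (lower E)."""
        ds = simulate(SimulationConfig(regime="dispersal", seed=2))
        g = ds.groups
        report = persimper_report(ds.matrix, g["1"], g["2"], n_perm=100, rng=0)
        assert report["dispersal"].e_values.mean() < report["niche"].e_values.mean()

    def test_classify_boundaries(self):
        assert classify(-2.0, -0.1) == "dispersal"
        assert classify(0.1, 2.0) == "niche"
        assert classify(-0.5, 0.5) == "both"


class TestDNCIMultigroup:
    def test_two_clusters_equal_single_pair(self, block_matrix):
        assignment = {f"L{i}": 1 if i < 4 else 2 for i in range(8)}
        overall, pairwise = dnci_multigroup(
            block_matrix, assignment, n_perm=50, rng=3
        )
        assert len(pairwise) == 1
        assert overall is pairwise[0].result

    def test_three_clusters_produce_three_pairs(self):
        ds = simulate(
            SimulationConfig(regime="dispersal", n_groups=3, n_levels_per_group=8, seed=3)
        )
        assignment = {
            lv: int(gid) for gid, levels in ds.groups.items() for lv in levels
        }
        overall, pairwise = dnci_multigroup(ds.matrix, assignment, n_perm=50, rng=2)
        assert len(pairwise) == 3
        assert {(p.cluster_a, p.cluster_b) for p in pairwise} == {(1, 2), (1, 3), (2, 3)}
        ok = [p.result.dnci for p in pairwise if p.result]
        assert overall.dnci == pytest.approx(np.mean(ok))

    def test_degenerate_pair_error_is_surfaced_not_raised(self):
        X = np.array([[1, 1], [1, 1], [1, 1], [1, 1], [1, 0], [0, 1]], dtype=np.int8)
        m = matrix_from(X)
        assignment = {"L0": 1, "L1": 1, "L2": 2, "L3": 2, "L4": 3, "L5": 3}
        overall, pairwise = dnci_multigroup(m, assignment, n_perm=30, rng=1)
        failed = [p for p in pairwise if p.result is None]
        assert failed and all(p.error for p in failed)

    def test_single_cluster_rejected(self, block_matrix):
        with pytest.raises(AnalysisNotPossibleError):
            dnci_multigroup(block_matrix, {f"L{i}": 1 for i in range(8)}, n_perm=20)
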