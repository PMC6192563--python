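import numpy as np
import pytest
import scipy.stats

from conndyn import (
    AssociationResult,
    RegionSet,
    StructuralConnectome,
    WilsonCowanParams,
    alternate_site_control,
    fdr_across_tasks,
    pearson_bootstrap,
    random_subnetwork_null,
    run_full_analysis,
)
from conndyn.association import annotate_fdr, enumerate_connected_sites, knn_adjacency

from conftest import make_connectome


def bh_stepup_oracle(p, alpha=0.05):
    """Independent brute-force Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= alpha * k / m:
            k_max = k
    flags = np.zeros(m, dtype=bool)
    flags[order[:k_max]] = True
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        adj[order[rank - 1]] = running
    return flags, adj


class TestPearsonBootstrap:
    def test_perfect_positive_relation(self):
        res = pearson_bootstrap([1, 2, 3], [2, 4, 6], n_boot=200, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_perfect_negative_relation(self):
        res = pearson_bootstrap([1, 2, 3], [-1, -2, -3], n_boot=200, seed=0)
        assert res.r == pytest.approx(-1.0)

    def test_closed_form_r(self):
        res = pearson_bootstrap([1, 2, 3, 4], [1, 3, 2, 4], n_boot=200, seed=0)
        assert res.r == pytest.approx(0.8)
        r_ref, p_ref = scipy.stats.pearsonr([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.p == pytest.approx(p_ref)

    def test_ci_brackets_point_estimate(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        y = 0.7 * x + rng.standard_normal(10)
        res = pearson_bootstrap(x, y, n_boot=2000, seed=1)
        assert res.ci_low <= res.r <= res.ci_high
        assert -1.0 <= res.ci_low < res.ci_high <= 1.0

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        x, y = rng.standard_normal((2, 8))
        a = pearson_bootstrap(x, y, n_boot=500, seed=3)
        b = pearson_bootstrap(x, y, n_boot=500, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero-variance"):
            pearson_bootstrap([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_bootstrap([1, 2], [1, 2])


class TestFDR:
    def test_all_significant_when_below_stepup_line(self):
        flags, _ = fdr_across_tasks([0.001, 0.02, 0.04])
        assert flags.all()

    def test_none_significant(self):
        flags, _ = fdr_across_tasks([0.5, 0.6, 0.7])
        assert not flags.any()

    def test_adjusted_values_example(self):
        flags, adj = fdr_across_tasks([0.01, 0.5, 0.9])
        np.testing.assert_allclose(adj, [0.03, 0.75, 0.9])
        assert list(flags) == [True, False, False]

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            p = rng.random(rng.integers(1, 8))
            flags, adj = fdr_across_tasks(p)
            eflags, eadj = bh_stepup_oracle(p)
            assert np.array_equal(flags, eflags)
            np.testing.assert_allclose(adj, eadj, rtol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_across_tasks([0.1, 1.5])
        with pytest.raises(ValueError):
            fdr_across_tasks([0.1, np.nan])

    def test_annotate_groups_by_feature_and_condition(self):
        mk = lambda f, t, c, p: AssociationResult(f, t, c, 0.5, p, 0, 1, 10)
        results = [mk("c5T", "VG", "before", 0.01),
                   mk("c5T", "SC", "before", 0.5),
                   mk("c5T", "NR", "before", 0.9),
                   mk("deg", "VG", "before", 0.04),
                   mk("deg", "SC", "before", 0.04),
                   mk("deg", "NR", "before", 0.04)]
        annotate_fdr(results)
        assert results[0].fdr_significant and not results[1].fdr_significant
        # the 'deg' family is corrected independently: all at 0.04 stay significant
        assert all(r.fdr_significant for r in results[3:])


class TestRandomSubnetworkNull:
    @staticmethod
    def fake_dfcs(n_subjects, n, seed):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n_subjects):
            M = rng.standard_normal((n, n)) * 0.1
            M = (M + M.T) / 2
            np.fill_diagonal(M, 0.0)
            out.append(M)
        return out

    def test_independent_behavior_gives_small_fraction(self):
        labels = [f"r{i}" for i in range(30)]
        dfcs = self.fake_dfcs(10, 30, seed=0)
        behavior = np.random.default_rng(1).standard_normal(10)
        circuit = RegionSet("c", tuple(labels[:8]))
        summary = random_subnetwork_null(dfcs, behavior, labels, circuit,
                                         circuit_size=8, n_draws=500, seed=2)
        assert summary.fraction_significant < 0.10
        assert summary.overlap_fraction.min() >= 0.0
        assert summary.overlap_fraction.max() <= 1.0

    def test_full_size_subset_equals_global_indicator(self):
        labels = [f"r{i}" for i in range(10)]
        dfcs = self.fake_dfcs(8, 10, seed=3)
        behavior = np.random.default_rng(4).standard_normal(8)
        circuit = RegionSet("c", tuple(labels[:4]))
        summary = random_subnetwork_null(dfcs, behavior, labels, circuit,
                                         circuit_size=10, n_draws=20, seed=5)
        effects = [M[np.triu_indices(10, 1)].mean() for M in dfcs]
        r, p = scipy.stats.pearsonr(effects, behavior)
        expected = float(r > 0.5 and p < 0.05)
        assert summary.fraction_significant == expected

    def test_parameter_errors(self):
        labels = ["a", "b", "c"]
        dfcs = self.fake_dfcs(3, 3, seed=0)
        circuit = RegionSet("c", ("a", "b"))
        with pytest.raises(ValueError, match="n_draws"):
            random_subnetwork_null(dfcs, [1, 2, 3], labels, circuit, n_draws=0)
        with pytest.raises(ValueError, match="circuit_size"):
            random_subnetwork_null(dfcs, [1, 2, 3], labels, circuit,
                                   circuit_size=1, n_draws=5)


class TestConnectedSites:
    def test_chain_enumeration(self):
        adj = np.zeros((5, 5), dtype=bool)
        for i in range(4):
            adj[i, i + 1] = adj[i + 1, i] = True
        sites = enumerate_connected_sites(adj, list(range(5)), 2)
        assert sites == [(0, 1), (1, 2), (2, 3), (3, 4)]

    def test_single_region_sites(self):
        adj = np.zeros((4, 4), dtype=bool)
        sites = enumerate_connected_sites(adj, list(range(4)), 1)
        assert sites == [(0,), (1,), (2,), (3,)]

    def test_size_exceeding_candidates_rejected(self):
        adj = np.ones((3, 3), dtype=bool)
        with pytest.raises(ValueError, match="exceeds"):
            enumerate_connected_sites(adj, [0, 1], 3)

    def test_disconnected_candidates_have_no_groups(self):
        adj = np.zeros((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="no connected group"):
            enumerate_connected_sites(adj, [0, 1, 2, 3], 2)

    def test_subsampling_reproducible(self):
        adj = np.ones((8, 8), dtype=bool) ^ np.eye(8, dtype=bool)
        a = enumerate_connected_sites(adj, list(range(8)), 3, max_sites=5, seed=1)
        b = enumerate_connected_sites(adj, list(range(8)), 3, max_sites=5, seed=1)
        assert a == b and len(a) == 5

    def test_knn_adjacency_symmetric(self, small_conn):
        adj = knn_adjacency(small_conn, k=3)
        assert np.array_equal(adj, adj.T)
        assert not np.diag(adj).any()
        assert adj.sum(1).min() >= 3  # symmetrized kNN has degree >= k


class TestAlternateSiteControl:
    def test_small_cohort_run(self):
        cohort = [make_connectome(n=16, density=0.35, seed=s, scale=3.0)
                  for s in range(3)]
        circuit = RegionSet("circ", tuple(cohort[0].labels[:8]))
        behavior = [900.0, 950.0, 1000.0]
        out = alternate_site_control(cohort, [0.06, 0.06, 0.06], circuit,
                                     behavior, WilsonCowanParams(),
                                     site_size=2, max_sites=2, seed=0,
                                     n_boot=100)
        assert len(out) == 2
        for site, assoc in out:
            assert len(site.labels) == 2
            assert set(site.labels) <= set(circuit.labels)
            assert -1.0 <= assoc.r <= 1.0

    def test_site_must_be_smaller_than_circuit(self):
        cohort = [make_connectome(n=10, seed=0)]
        circuit = RegionSet("c", tuple(cohort[0].labels[:4]))
        with pytest.raises(ValueError, match="larger"):
            alternate_site_control(cohort, [0.06], circuit, [1.0],
                                   WilsonCowanParams(), site_size=4)


def test_run_full_analysis_rejects_empty_cohort():
    with pytest.raises(ValueError, match="empty"):
        run_full_analysis([], None, None, None)
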