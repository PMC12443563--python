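import numpy as np
import pytest
from scipy import stats

from dysfunctome.connectivity import ConnectivityMatrix
from dysfunctome.nbs import (
    DegenerateDesignError,
    NbsConfig,
    NetworkComponent,
    StatisticMatrix,
    SweepResult,
    TauResult,
    choose_dysfunctome,
    component_p,
    component_severity_correlation,
    components,
    edge_regression,
    min_component_size,
    permutation_null,
    select_component,
    threshold_matrix,
    threshold_sweep,
)
from dysfunctome.synthetic import CohortSpec, simulate_matrices


def random_matrices(n_subjects=8, n_channels=5, seed=0):
    rng = np.random.default_rng(seed)
    labels = tuple(f"c{i}" for i in range(n_channels))
    mats = []
    for _ in range(n_subjects):
        W = rng.uniform(0, 1, (n_channels, n_channels))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        mats.append(ConnectivityMatrix(labels=labels, W=W))
    return mats, rng.uniform(20, 95, n_subjects)


class TestEdgeRegression:
    def test_r_to_t_identity(self):
        # r = 0.5 at n = 15 -> t = 0.5 * sqrt(13 / 0.75)
        from dysfunctome.nbs import _r_to_t

        assert _r_to_t(np.array(0.5), 13) == pytest.approx(2.0817, abs=1e-4)

    def test_matches_per_edge_linregress(self):
        mats, scores = random_matrices(seed=3)
        stat = edge_regression(mats, scores)
        n = len(mats[0].labels)
        for i in range(n):
            for j in range(i + 1, n):
                y = np.array([m.W[i, j] for m in mats])
                res = stats.linregress(scores, y)
                t_ref = res.slope / res.stderr
                assert stat.T[i, j] == pytest.approx(t_ref, abs=1e-10)

    def test_constant_edge_gets_zero(self):
        mats, scores = random_matrices(seed=4)
        for m in mats:
            m.W[0, 1] = m.W[1, 0] = 0.5
        stat = edge_regression(mats, scores)
        assert stat.T[0, 1] == 0.0

    def test_perfect_fit_capped_and_flagged(self):
        mats, scores = random_matrices(seed=5)
        z = (scores - scores.mean()) / scores.std()
        for m, zz in zip(mats, z):
            m.W[0, 1] = m.W[1, 0] = 0.5 + 0.01 * zz
        stat = edge_regression(mats, scores)
        assert stat.T[0, 1] >= 1e6
        assert ("c0", "c1") in stat.capped_edges

    def test_constant_scores_rejected(self):
        mats, _ = random_matrices()
        with pytest.raises(DegenerateDesignError):
            edge_regression(mats, np.full(len(mats), 50.0))


class TestThresholdAndComponents:
    def make_stat(self, T):
        n = T.shape[0]
        return StatisticMatrix(labels=tuple(f"c{i}" for i in range(n)), T=T, df=10)

    def test_strict_inequality_at_threshold(self):
        T = np.zeros((3, 3))
        T[0, 1] = T[1, 0] = 2.0
        T[1, 2] = T[2, 1] = 2.5
        adj = threshold_matrix(self.make_stat(T), 2.0)
        assert not adj[0, 1] and adj[1, 2]

    def test_all_below_gives_empty(self):
        T = np.full((4, 4), 1.0)
        np.fill_diagonal(T, 0)
        adj = threshold_matrix(self.make_stat(T), 3.0)
        assert components(adj, tuple("abcd")) == []

    def test_very_low_threshold_gives_complete_graph(self):
        rng = np.random.default_rng(0)
        T = rng.uniform(1, 3, (5, 5))
        T = (T + T.T) / 2
        adj = threshold_matrix(self.make_stat(T), -100.0)
        comps = components(adj, tuple("abcde"))
        assert len(comps) == 1 and comps[0].size == 10

    def test_component_sizes_in_edges(self):
        labels = ("A", "B", "C", "D", "E")
        adj = np.zeros((5, 5), dtype=bool)
        for a, b in [(0, 1), (1, 2), (3, 4)]:
            adj[a, b] = adj[b, a] = True
        comps = components(adj, labels)
        assert [c.size for c in comps] == [2, 1]
        assert comps[0].nodes == {"A", "B", "C"}

    def test_ring_is_single_component(self):
        adj = np.zeros((5, 5), dtype=bool)
        for i in range(5):
            adj[i, (i + 1) % 5] = adj[(i + 1) % 5, i] = True
        comps = components(adj, tuple("abcde"))
        assert len(comps) == 1 and comps[0].size == 5


class TestPermutationInference:
    def test_null_reproducible_and_sized(self):
        mats, scores = random_matrices(seed=7)
        a = permutation_null(mats, scores, tau=2.0, n_perm=50, seed=9)
        b = permutation_null(mats, scores, tau=2.0, n_perm=50, seed=9)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 50

    def test_component_p_conventions(self):
        assert component_p(10, np.zeros(10000)) == pytest.approx(1 / 10001)
        assert component_p(0, np.ones(100)) == 1.0
        assert component_p(5, np.array([5])) == 1.0

    def test_null_rate_not_anticonservative(self):
        # beta = 0 cohorts: rejection rate at alpha=0.05 stays near nominal
        hits = 0
        n_cohorts = 100
        for i in range(n_cohorts):
            cohort = simulate_matrices(
                CohortSpec(seed=5000 + i, coupling_slope=0.0, n_channels=20)
            )
            stat = edge_regression(cohort.matrices, cohort.severity)
            null = permutation_null(
                cohort.matrices, cohort.severity, tau=2.5, n_perm=200, seed=6000 + i
            )
            comps = components(threshold_matrix(stat, 2.5), stat.labels)
            if comps and component_p(comps[0].size, null) < 0.05:
                hits += 1
        assert hits / n_cohorts < 0.11  # binomial upper band around 0.05


class TestSweepAndSelection:
    def test_grid_has_eleven_entries(self):
        mats, scores = random_matrices(n_subjects=10, seed=11)
        sweep = threshold_sweep(mats, scores, NbsConfig(n_perm=20, seed=0))
        assert len(sweep.results) == 11
        assert sweep.results[0].tau == 2.0 and sweep.results[-1].tau == 4.0

    def test_max_size_non_increasing_in_tau(self):
        cohort = simulate_matrices(CohortSpec(seed=13))
        sweep = threshold_sweep(cohort.matrices, cohort.severity, NbsConfig(n_perm=10, seed=0))
        sizes = [r.max_size for r in sweep.results]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_planted_cohort_detected(self):
        cohort = simulate_matrices(CohortSpec(seed=17))
        sweep = threshold_sweep(
            cohort.matrices, cohort.severity, NbsConfig(n_perm=500, seed=17)
        )
        assert any(
            c.p_value < 0.05 for res in sweep.results for c in res.components
        )

    def test_minimum_size_rule(self):
        assert min_component_size(61, 0.03) == 55

    def fabricate_sweep(self, entries, labels=tuple(f"c{i}" for i in range(61))):
        results = []
        for tau, size, p in entries:
            edges = tuple((f"n{k}", f"n{k + 1}") for k in range(size))
            comp = NetworkComponent(edges=edges, tau=tau, p_value=p)
            results.append(TauResult(tau=tau, components=[comp], null_max=np.zeros(1)))
        stat = StatisticMatrix(labels=labels, T=np.zeros((61, 61)), df=13)
        return SweepResult(stat=stat, results=results, config=NbsConfig(n_perm=1))

    def test_selects_highest_tau_meeting_floor(self):
        sweep = self.fabricate_sweep([(2.4, 80, 0.01), (3.0, 60, 0.01), (3.4, 40, 0.01)])
        chosen = select_component(sweep, n_channels=61, min_edge_frac=0.03)
        assert chosen.size == 60 and chosen.tau == 3.0

    def test_none_when_nothing_significant(self):
        sweep = self.fabricate_sweep([(2.4, 80, 0.5), (3.0, 60, 0.2)])
        assert select_component(sweep, n_channels=61, min_edge_frac=0.03) is None


class TestComponentCorrelationAndChoice:
    def test_all_edge_component_matches_whole_matrix_mean(self):
        mats, scores = random_matrices(n_subjects=10, seed=19)
        labels = mats[0].labels
        edges = tuple(
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        )
        comp = NetworkComponent(edges=edges)
        r, _ = component_severity_correlation(mats, comp, scores)
        iu, ju = np.triu_indices(len(labels), 1)
        means = [m.W[iu, ju].mean() for m in mats]
        assert r == pytest.approx(stats.pearsonr(means, scores)[0], abs=1e-12)

    def test_planted_component_recovers_strong_r(self):
        cohort = simulate_matrices(CohortSpec(seed=23, noise_sd=1e-6))
        comp = NetworkComponent(edges=tuple(map(tuple, cohort.ground_truth["planted_edges"])))
        r, _ = component_severity_correlation(cohort.matrices, comp, cohort.severity)
        assert r > 0.999

    def test_choose_highest_r_then_tau_then_condition(self):
        def cand(r, tau, cond):
            return NetworkComponent(
                edges=(("a", "b"),), tau=tau, p_value=0.01, condition=cond, r=r
            )

        best = choose_dysfunctome([cand(0.873, 2.8, "x"), cand(0.845, 3.0, "y"), cand(0.877, 3.0, "z")])
        assert best.r == 0.877
        tied = choose_dysfunctome([cand(0.8, 2.8, "x"), cand(0.8, 3.4, "y")])
        assert tied.tau == 3.4
        tied2 = choose_dysfunctome([cand(0.8, 3.0, "b"), cand(0.8, 3.0, "a")])
        assert tied2.condition == "a"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            choose_dysfunctome([])
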