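"""Dirichlet-process mixture clustering: conjugacy, recovery, invariants."""

import numpy as np
import pytest

from somaclone import gibbs_run, point_estimate, sample_theta
from somaclone.cluster import DegeneratePartitionError, EmptyInputError
from somaclone.evaluate import adjusted_rand

from conftest import make_table


def two_cluster_benchmark(seed, n_per=100, depth=40):
    """100+100 mutations with per-sample VAFs (0.5, 0) vs (0.25, 0.25)."""
    rng = np.random.default_rng(seed)
    vafs = np.array([[0.5, 0.0]] * n_per + [[0.25, 0.25]] * n_per)
    depths = np.full((2 * n_per, 2), depth)
    alt = rng.binomial(depths, vafs)
    labels = np.array([0] * n_per + [1] * n_per)
    return make_table(alt, depths), labels


class TestGibbsRun:
    def test_single_mutation_single_cluster(self):
        table = make_table([[10, 0]], [[20, 20]])
        trace = gibbs_run(table, n_iter=50, burn_in=10, seed=1)
        assert (trace.cluster_counts() == 1).all()

    def test_empty_input_raises(self):
        table, _ = two_cluster_benchmark(0)
        with pytest.raises(EmptyInputError):
            gibbs_run(table.subset(np.zeros(table.n_sites, bool)))

    def test_theta_conditional_matches_conjugate_posterior(self):
        """With the partition fixed, theta_{k,s} ~ Beta(1 + sum alt,
        1 + sum(depth - alt)); the sampler's mean must agree with the
        closed form within 3 Monte-Carlo standard errors."""
        rng = np.random.default_rng(5)
        alt = rng.binomial(40, 0.3, size=(30, 3))
        depth = np.full((30, 3), 40)
        assignment = np.array([0] * 15 + [1] * 15)
        draws = sample_theta(alt, depth, assignment, n_draws=4000, seed=9)
        for i, k in enumerate([0, 1]):
            a = 1 + alt[assignment == k].sum(axis=0)
            b = 1 + (depth - alt)[assignment == k].sum(axis=0)
            expected = a / (a + b)
            sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
            mc_se = sd / np.sqrt(draws.shape[0])
            assert (np.abs(draws[:, i].mean(axis=0) - expected) < 3 * mc_se).all()

    def test_two_cluster_recovery(self):
        table, labels = two_cluster_benchmark(2)
        trace = gibbs_run(table, n_iter=600, burn_in=200, seed=2)
        clusters = point_estimate(trace)
        z = np.empty(table.n_sites, int)
        for cl in clusters:
            z[table.site_ids.get_indexer(cl.members)] = cl.cluster_id
        assert adjusted_rand(z, labels) >= 0.95
        # theta close to truth per sample
        truth_theta = {0: [0.5, 0.0], 1: [0.25, 0.25]}
        for cl in clusters:
            true_label = labels[table.site_ids.get_indexer(cl.members)].mean().round()
            expect = truth_theta[int(true_label)]
            assert np.abs(cl.theta_hat.to_numpy() - expect).max() < 0.05

    def test_seeded_determinism(self):
        table, _ = two_cluster_benchmark(3, n_per=30)
        a = gibbs_run(table, n_iter=100, burn_in=50, seed=7)
        b = gibbs_run(table, n_iter=100, burn_in=50, seed=7)
        assert (a.assignments == b.assignments).all()
        assert (a.alphas == b.alphas).all()

    def test_ari_against_sklearn_reference(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        x = rng.integers(0, 4, 50)
        y = rng.integers(0, 3, 50)
        assert adjusted_rand(x, y) == pytest.approx(adjusted_rand_score(x, y))

    def test_low_fixed_alpha_concentrates_on_one_cluster(self):
        rng = np.random.default_rng(8)
        depth = np.full((80, 3), 40)
        alt = rng.binomial(depth, 0.25)
        trace = gibbs_run(
            make_table(alt, depth), n_iter=300, burn_in=100, seed=8, fixed_alpha=1e-6
        )
        assert (trace.cluster_counts() == 1).mean() >= 0.99

    def test_exchangeability_under_input_permutation(self):
        table, labels = two_cluster_benchmark(4)
        ref = gibbs_run(table, n_iter=400, burn_in=150, seed=4)
        z_ref = ref.assignments[-1]
        rng = np.random.default_rng(0)
        perm = rng.permutation(table.n_sites)
        table_p = table.subset(table.site_ids[perm])
        out = gibbs_run(table_p, n_iter=400, burn_in=150, seed=5)
        z_perm = np.empty_like(z_ref)
        z_perm[perm] = out.assignments[-1]
        ari_ref = adjusted_rand(z_ref, labels)
        ari_perm = adjusted_rand(z_perm, labels)
        assert abs(ari_ref - ari_perm) < 0.02

    def test_recovery_improves_with_depth(self):
        """ARI at depth 100 is at least as good as at depth 10, on average
        over matched seeds (graceful degradation with coverage)."""
        aris = {10: [], 100: []}
        for seed in range(10):
            for depth in (10, 100):
                table, labels = two_cluster_benchmark(seed + 50, n_per=40, depth=depth)
                trace = gibbs_run(table, n_iter=300, burn_in=100, seed=seed)
                clusters = point_estimate(trace, min_cluster_size=2)
                z = np.empty(table.n_sites, int)
                for cl in clusters:
                    z[table.site_ids.get_indexer(cl.members)] = cl.cluster_id
                aris[depth].append(adjusted_rand(z, labels))
        assert np.mean(aris[100]) >= np.mean(aris[10])


class TestTrace:
    def test_co_assignment_properties(self):
        table, _ = two_cluster_benchmark(6, n_per=20)
        trace = gibbs_run(table, n_iter=200, burn_in=80, seed=6)
        co = trace.co_assignment().to_numpy()
        assert np.allclose(co, co.T)
        assert np.allclose(np.diag(co), 1.0)
        assert co.min() >= 0 and co.max() <= 1

    def test_co_assignment_invariant_to_relabelling(self):
        table, _ = two_cluster_benchmark(6, n_per=15)
        trace = gibbs_run(table, n_iter=150, burn_in=50, seed=6)
        co1 = trace.co_assignment().to_numpy()
        # relabel every retained state with a fixed permutation of labels
        trace.assignments = trace.assignments.max() + 1 - trace.assignments
        co2 = trace.co_assignment().to_numpy()
        assert np.allclose(co1, co2)


class TestPointEstimate:
    def test_single_cluster_truth(self):
        rng = np.random.default_rng(1)
        depth = np.full((40, 2), 40)
        alt = rng.binomial(depth, 0.25)
        trace = gibbs_run(make_table(alt, depth), n_iter=200, burn_in=80, seed=1)
        clusters = point_estimate(trace)
        assert len(clusters) == 1
        assert clusters[0].burden == 40

    def test_burdens_partition_the_mutations(self):
        table, _ = two_cluster_benchmark(9)
        trace = gibbs_run(table, n_iter=300, burn_in=100, seed=9)
        clusters = point_estimate(trace)
        assert sum(cl.burden for cl in clusters) == table.n_sites
        all_members = [m for cl in clusters for m in cl.members]
        assert sorted(all_members) == sorted(table.site_ids)

    def test_small_clusters_dissolved(self):
        table, labels = two_cluster_benchmark(10, n_per=50)
        trace = gibbs_run(table, n_iter=300, burn_in=100, seed=10)
        clusters = point_estimate(trace, min_cluster_size=5)
        assert all(cl.burden >= 5 for cl in clusters)

    def test_degenerate_partition_error(self):
        table = make_table([[10, 0], [0, 10]], [[20, 20], [20, 20]])
        trace = gibbs_run(table, n_iter=60, burn_in=20, seed=3)
        with pytest.raises(DegeneratePartitionError):
            point_estimate(trace, min_cluster_size=5)

    def test_prevalence_is_capped_doubled_theta(self):
        table, _ = two_cluster_benchmark(12, n_per=40)
        trace = gibbs_run(table, n_iter=200, burn_in=80, seed=12)
        for cl in point_estimate(trace):
            np.testing.assert_allclose(
                cl.prevalence.to_numpy(),
                np.minimum(1.0, 2 * cl.theta_hat.to_numpy()),
            )
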