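"""Large-K objects: atomic-measure flow and McKean-Vlasov particles."""

import numpy as np
import pytest

from metamoran import (
    AtomicMeasure,
    chaos_diagnostics,
    evolve_atomic_measure,
    preset_kernels,
    simulate_mckean_vlasov,
    solve_replicator,
    build_interaction_matrix,
    two_trait_kernels,
)


class TestAtomicMeasure:
    def test_total_mass_and_marginal(self):
        mu = AtomicMeasure([0.2, 0.2, 0.8], [[0.0], [1.0], [0.0]], [0.5, 0.25, 0.25])
        assert mu.total_mass == pytest.approx(1.0)
        traits, weights = mu.trait_marginal()
        agg = dict(zip(traits[:, 0], weights))
        assert agg[0.0] == pytest.approx(0.75)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            AtomicMeasure([0.5], [[0.0]], [-0.1])


class TestMeasureFlow:
    def test_monomorphic_measure_is_a_fixed_point(self):
        """A metapopulation monomorphic from the start stays constant."""
        kern = preset_kernels("neutral", N=5, theta0=0.0, lam0=1.0)
        nu0 = AtomicMeasure([0.5], [[0.5]], [1.0])
        traj = evolve_atomic_measure(nu0, kern, 10.0)
        assert np.abs(traj.weights - traj.weights[0]).max() == 0.0

    def test_mass_conserved_to_tight_tolerance(self):
        kern = preset_kernels("case1_exclusion", N=5)
        nu0 = AtomicMeasure(
            np.repeat([0.25, 0.75], 3),
            np.tile([[0.2], [0.5], [0.8]], (2, 1)),
            [0.2, 0.2, 0.1, 0.1, 0.2, 0.2],
        )
        traj = evolve_atomic_measure(nu0, kern, 50.0)
        assert np.abs(traj.mass() - 1.0).max() < 1e-10

    def test_deterministic_flow_is_bit_identical_across_runs(self):
        kern = preset_kernels("case2_cycling", N=5)
        nu0 = AtomicMeasure(np.full(3, 0.5), [[0.2], [0.5], [0.8]], np.full(3, 1 / 3))
        a = evolve_atomic_measure(nu0, kern, 20.0)
        b = evolve_atomic_measure(nu0, kern, 20.0)
        assert np.array_equal(a.weights, b.weights)

    def test_mutation_free_flow_matches_replicator_mean_weights(self):
        kern = preset_kernels("case1_exclusion", N=5)
        traits = [0.2, 0.5, 0.8]
        w0 = np.full(3, 1 / 3)
        nu0 = AtomicMeasure(np.full(3, 0.5), np.reshape(traits, (3, 1)), w0)
        t_eval = np.linspace(0, 20, 21)
        flow = evolve_atomic_measure(nu0, kern, 20.0, t_eval=t_eval)
        _, W = solve_replicator(build_interaction_matrix(traits, kern), w0, 20.0, t_eval=t_eval)
        assert np.abs(flow.trait_mean_weights() - W).max() < 1e-7

    def test_discrete_mutation_closes_the_flow(self):
        # two-trait discrete mutation: support closure adds the partner trait
        kern = two_trait_kernels(N=4, c_ab=2.0, c_ba=1.0, theta0=0.5, lam0=0.0)
        nu0 = AtomicMeasure([0.5], [[0.0]], [1.0])
        traj = evolve_atomic_measure(nu0, kern, 5.0)
        assert traj.traits.shape[0] == 2
        assert np.abs(traj.mass() - 1.0).max() < 1e-10
        # selection favours trait b: its weight should grow
        final = traj.weights[-1].sum(axis=0)
        assert final[1] > final[0]

    def test_continuous_mutation_is_rejected_with_pointer(self):
        kern = preset_kernels("neutral", N=5, theta0=1.0, lam0=0.0)
        nu0 = AtomicMeasure([0.5], [[0.0]], [1.0])
        with pytest.raises(ValueError, match="mckean_vlasov"):
            evolve_atomic_measure(nu0, kern, 1.0)


class TestParticles:
    def test_frozen_without_mutation_and_monomorphic_start(self):
        kern = preset_kernels("neutral", N=5, theta0=0.0, lam0=1.0)
        traj = simulate_mckean_vlasov(np.zeros((50, 1)), kern, 50, 5.0, seed=1)
        assert np.all(traj.final_traits == 0.0)
        assert traj.jump_counts.sum() == 0

    def test_independent_particles_substitutions_poisson(self):
        # lam = 0, neutral, theta constant: each particle is an independent
        # substitution sequence with rate theta
        theta, T, M = 0.7, 4.0, 400
        kern = preset_kernels("neutral", N=4, theta0=theta, lam0=0.0)
        traj = simulate_mckean_vlasov(np.zeros((M, 1)), kern, M, T, seed=2)
        mean = traj.jump_counts.mean()
        se = np.sqrt(theta * T / M)
        assert abs(mean - theta * T) < 3 * se

    def test_two_trait_frequency_follows_replicator_ode(self):
        """LLN consistency: with mutation off, the particle frequency path
        matches the replicator solution for the same interaction."""
        kern = preset_kernels("case1_exclusion", N=5)
        traits = [0.2, 0.8]
        M, T = 2000, 6.0
        rng = np.random.default_rng(5)
        x0 = np.where(rng.random((M, 1)) < 0.5, 0.2, 0.8)
        traj = simulate_mckean_vlasov(x0, kern, M, T, seed=6, record_times=[T])
        freq = (traj.snapshots[-1][:, 0] == 0.2).mean()
        _, W = solve_replicator(build_interaction_matrix(traits, kern), [0.5, 0.5], T)
        target = W[-1, 0]
        se = np.sqrt(target * (1 - target) / M)
        # MC error plus O(1/M) interaction bias
        assert abs(freq - target) < 3 * se + 5.0 / M

    def test_heterogeneous_kernels_rejected(self):
        kern = preset_kernels("neutral", N=5)
        object.__setattr__(kern, "homogeneous", False)
        with pytest.raises(ValueError, match="homogeneous"):
            simulate_mckean_vlasov(np.zeros((10, 1)), kern, 10, 1.0, seed=0)


class TestChaosDiagnostics:
    def test_independent_statistics_sit_in_the_null_band(self, rng):
        stats = {100: rng.standard_normal((500, 6))}
        rep = chaos_diagnostics(stats)
        assert abs(rep["correlations"][100]["mean"]) < rep["correlations"][100]["null_band"]

    def test_duplicated_trajectories_have_correlation_one(self, rng):
        col = rng.standard_normal(300)
        rep = chaos_diagnostics({7: np.column_stack([col, col])})
        assert rep["correlations"][7]["mean"] == pytest.approx(1.0)

    def test_insufficient_replicates_is_an_error(self, rng):
        with pytest.raises(ValueError, match="replicates"):
            chaos_diagnostics({10: rng.standard_normal((50, 4))})
        with pytest.raises(ValueError, match="tagged"):
            chaos_diagnostics({10: rng.standard_normal((200, 1))})

    def test_particle_law_approaches_measure_flow_with_m(self):
        """KS-type distance between the particle marginal and the atomic
        flow's trait weights decreases from M = 200 to M = 2000."""
        kern = preset_kernels("case1_exclusion", N=5)
        traits = [0.2, 0.8]
        T = 6.0
        nu0 = AtomicMeasure(np.full(2, 0.5), np.reshape(traits, (2, 1)), [0.5, 0.5])
        flow = evolve_atomic_measure(nu0, kern, T, t_eval=[0.0, T])
        target = flow.trait_mean_weights()[-1][0]
        errs = {}
        for M in (200, 2000):
            reps = []
            for seed in range(5):
                rng = np.random.default_rng(seed)
                x0 = np.where(rng.random((M, 1)) < 0.5, 0.2, 0.8)
                traj = simulate_mckean_vlasov(x0, kern, M, T, seed=seed + 100)
                reps.append(abs((traj.final_traits[:, 0] == 0.2).mean() - target))
            errs[M] = np.mean(reps)
        assert errs[2000] < errs[200]
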