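"""Canonical jump-diffusion: coefficients, environment and tagged paths."""

import numpy as np
import pytest
from scipy.stats import kstest

from metamoran import (
    CanonicalConfig,
    EnvironmentEnsemble,
    drift_diffusion_coeffs,
    preset_kernels,
    simulate_canonical_homogeneous,
    simulate_environment,
    simulate_tagged,
)
from metamoran.canonical import rescaled_small_mutation_kernels
from metamoran.kernels import ModelKernels


class TestCoefficients:
    def test_single_individual_deme_has_no_advection(self):
        # the (N - 1)/2 factor kills selection exactly at N = 1
        kern = preset_kernels("gaussian_stabilizing", N=1, s=3.0)
        drift, _ = drift_diffusion_coeffs(kern, 0.5, 0.9)
        assert np.all(drift == 0.0)

    def test_neutral_coefficients(self):
        kern = preset_kernels("neutral", N=5, theta0=0.49)
        drift, difffac = drift_diffusion_coeffs(kern, 0.5, 0.2)
        assert drift == pytest.approx(np.zeros(1), abs=1e-9)
        assert difffac[0, 0] == pytest.approx(np.sqrt(0.49))

    def test_directional_drift_closed_form(self):
        # Fit = 2 s (y - x): drift = (N - 1)/2 * theta * Sigma * 2s = (N-1) theta s
        s, theta, N = 0.4, 0.8, 6
        kern = preset_kernels("directional_1d", N=N, s=s, theta0=theta)
        drift, _ = drift_diffusion_coeffs(kern, 0.5, 0.5)
        assert drift[0] == pytest.approx((N - 1) * theta * s, rel=1e-6)


class TestEnvironment:
    def test_frozen_when_steps_and_migration_vanish(self):
        kern = ModelKernels(
            N=5, d=1,
            c=lambda r, x, y: 1.0,
            theta=lambda r, x: 1.0,
            lam=lambda r, x, r2, y: 0.0,
            m_sampler=lambda g, r, x: np.zeros(1),
            Sigma_exact=lambda r, x: np.zeros((1, 1)),
            c_bar=1.0, theta_bar=1.0, lam_bar=0.0,
        )
        xi0 = EnvironmentEnsemble(np.linspace(0, 1, 20), np.full((20, 1), 0.3))
        env = simulate_environment(xi0, kern, 1.0, dt=0.05, seed=0)
        assert np.all(env.snapshots[-1] == 0.3)

    def test_diffusion_only_variance(self):
        # Var(X_t) = theta Sigma t for neutral, lam = 0, constant coefficients
        theta, T, M = 0.5, 1.0, 800
        kern = preset_kernels("neutral", N=5, theta0=theta, lam0=0.0)
        xi0 = EnvironmentEnsemble(np.full(M, 0.5), np.zeros((M, 1)))
        env = simulate_environment(xi0, kern, T, dt=0.02, seed=21, record_times=[T])
        var = env.snapshots[-1].var(ddof=1)
        se = np.sqrt(2 / (M - 1)) * theta * T
        assert abs(var - theta * T) < 3 * se

    def test_jump_frequency_matches_kernel_rate(self):
        """Empirical exchange-jump rate = N^2 * mean(lam * alpha) under
        neutral resampling with constant lam."""
        N, lam0, T, M = 3, 0.4, 2.0, 500
        kern = preset_kernels("neutral", N=N, theta0=0.2, lam0=lam0)
        rng = np.random.default_rng(3)
        xi0 = EnvironmentEnsemble(rng.uniform(size=M), rng.standard_normal((M, 1)))
        env = simulate_environment(xi0, kern, T, dt=0.02, seed=31)
        expected = N**2 * lam0 * (1 / N) * T  # alpha = 1/N, traits a.s. distinct
        mean = env.jump_counts.mean()
        se = np.sqrt(expected / M)
        assert abs(mean - expected) < 3 * se


class TestTagged:
    def test_pure_diffusion_path_law_is_gaussian(self):
        """lam = 0: the tagged path is Brownian; X_T ~ N(x0, theta T)."""
        theta, T = 0.6, 0.5
        kern = preset_kernels("neutral", N=5, theta0=theta, lam0=0.0)
        M = 50
        xi0 = EnvironmentEnsemble(np.full(M, 0.5), np.zeros((M, 1)))
        env = simulate_environment(xi0, kern, T, dt=0.01, seed=41)
        cfg = CanonicalConfig(kernels=kern, z=0.5, M=M, dt=0.01, t_end=T, seed=42)
        paths = simulate_tagged(np.zeros((1, 1)), cfg, env, n_paths=400)
        end = paths.paths[-1][:, 0]
        res = kstest(end, "norm", args=(0.0, np.sqrt(theta * T)))
        assert res.pvalue > 0.01
        assert paths.jump_counts.sum() == 0

    def test_euler_error_halves_with_dt_on_deterministic_drift(self):
        """sigma = 0, lam = 0: the scheme reduces to explicit Euler on
        x' = drift(x); halving dt halves the error (first order)."""
        kern = ModelKernels(
            N=5, d=1,
            c=lambda r, x, y: float(np.exp(0.5 * (float(np.atleast_1d(x)[0]) ** 2 - float(np.atleast_1d(y)[0]) ** 2))),
            theta=lambda r, x: 1.0,
            lam=lambda r, x, r2, y: 0.0,
            m_sampler=lambda g, r, x: np.zeros(1),
            Sigma_exact=lambda r, x: np.eye(1),  # Sigma enters drift only
            c_bar=10.0, theta_bar=1.0, lam_bar=0.0,
        )
        # Fit(y, x) = x^2 - y^2, so drift = (N-1)/2 * theta * grad_y Fit = -4x;
        # only the drift update is exercised below, so no noise enters
        x0 = 1.0

        def euler_final(dt):
            x = x0
            n = int(round(1.0 / dt))
            for _ in range(n):
                d, _ = drift_diffusion_coeffs(kern, 0.5, x)
                x = x + float(d[0]) * dt
            return x

        exact = x0 * np.exp(-4.0)  # x' = -4x over t in [0, 1]
        e1 = abs(euler_final(0.02) - exact)
        e2 = abs(euler_final(0.01) - exact)
        assert 1.5 < e1 / e2 < 2.5

    def test_grid_mismatch_is_an_error(self):
        kern = preset_kernels("neutral", N=5, theta0=0.1, lam0=0.0)
        xi0 = EnvironmentEnsemble(np.full(10, 0.5), np.zeros((10, 1)))
        env = simulate_environment(xi0, kern, 0.5, dt=0.05, seed=1)
        cfg = CanonicalConfig(kernels=kern, z=0.5, M=10, dt=0.01, t_end=0.5, seed=2)
        with pytest.raises(ValueError, match="Euler grid"):
            simulate_tagged(np.zeros((1, 1)), cfg, env)


class TestHomogeneousEnsemble:
    def test_minimal_ensemble_runs(self):
        kern = preset_kernels("neutral", N=3, theta0=0.5, lam0=0.5)
        traj = simulate_canonical_homogeneous(
            lambda rng, m: np.zeros((m, 1)), kern, 2, 0.2, dt=0.05, seed=5
        )
        assert traj.snapshots.shape[1] == 2

    def test_stabilizing_selection_pulls_mean_to_optimum(self):
        kern = preset_kernels("gaussian_stabilizing", N=6, s=2.0, x0=0.0, theta0=1.0, lam0=0.1, box=(-4, 4))
        traj = simulate_canonical_homogeneous(
            lambda rng, m: rng.normal(1.5, 0.1, size=(m, 1)), kern, 300, 2.0, dt=0.02, seed=6,
            record_times=[0.0, 2.0],
        )
        start = abs(traj.snapshots[0].mean())
        end = abs(traj.snapshots[-1].mean())
        assert end < start / 3


class TestRescaling:
    def test_rescaled_kernels_shrink_steps_and_migration(self):
        kern = preset_kernels("neutral", N=3, theta0=1.0, lam0=0.8)
        ke = rescaled_small_mutation_kernels(kern, 0.1)
        assert ke.lam_bar == pytest.approx(0.8 * 0.01)
        assert ke.lam(0.5, 0.0, 0.5, 1.0) == pytest.approx(0.8 * 0.01)
        rng = np.random.default_rng(0)
        steps = np.array([ke.Q_sampler(rng, 0.5, np.zeros(1))[0] for _ in range(200)])
        assert np.std(steps) == pytest.approx(0.1, rel=0.2)

    def test_requires_step_sampler(self):
        kern = preset_kernels("case1_exclusion", N=3)
        with pytest.raises(ValueError, match="m_sampler"):
            rescaled_small_mutation_kernels(kern, 0.1)
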