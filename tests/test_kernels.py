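"""Fixation probability, fitness and mutation-covariance primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metamoran import (
    fixation_gradient,
    fixation_oracle,
    fixation_probability,
    mutation_covariance,
    preset_kernels,
    relative_fitness,
    selection_gradient,
    ModelKernels,
)


@pytest.mark.parametrize(
    "cf, cb, N, expected",
    [
        (1.0, 1.0, 5, 1 / 5),        # neutral invader fixes with probability 1/N
        (0.0, 3.0, 3, 0.0),          # an invader that never displaces residents
        (1.0, 2.0, 3, 1 / 7),        # geometric sum 1 + 2 + 4
        (0.3, 7.0, 1, 1.0),          # single-slot deme: arrival is fixation
        (5.0, 1e-300, 4, 1.0),       # overwhelming advantage
    ],
)
def test_fixation_probability_closed_form(cf, cb, N, expected):
    assert fixation_probability(cf, cb, N) == pytest.approx(expected, abs=1e-15)


def test_fixation_probability_strong_counterselection_is_stable():
    # rho^N overflows a float; the log-space branch must return the tiny
    # positive value (rho - 1) rho^-N without inf/nan
    val = fixation_probability(1.0, 10.0, 300)
    assert val == pytest.approx(math.exp(math.log(9.0) - 300 * math.log(10.0)), rel=1e-10)
    assert np.isfinite(fixation_probability(1.0, 1e6, 400))


@pytest.mark.parametrize("bad", [dict(c_forward=-1, c_backward=1, N=3), dict(c_forward=1, c_backward=-2, N=3), dict(c_forward=1, c_backward=1, N=0)])
def test_fixation_probability_domain_errors(bad):
    with pytest.raises(ValueError):
        fixation_probability(bad["c_forward"], bad["c_backward"], bad["N"])
    with pytest.raises(ValueError):
        fixation_oracle(bad["c_forward"], bad["c_backward"], bad["N"])


def test_fixation_oracle_hand_values():
    # symmetric chain: neutral hitting probability 1/N
    assert fixation_oracle(1.0, 1.0, 4) == pytest.approx(0.25, abs=1e-12)
    # 2x2 interior system solved by hand gives 1/7
    assert fixation_oracle(1.0, 2.0, 3) == pytest.approx(1 / 7, abs=1e-12)


@settings(deadline=None, max_examples=120)
@given(
    rho=st.floats(min_value=0.1, max_value=10.0),
    N=st.integers(min_value=1, max_value=20),
)
def test_closed_form_matches_birth_death_solve(rho, N):
    """The geometric closed form and the first-step linear system agree."""
    assert fixation_probability(1.0, rho, N) == pytest.approx(fixation_oracle(1.0, rho, N), abs=1e-12)


def test_fixation_monotone_in_disadvantage():
    """More reverse resampling (larger rho) always lowers fixation."""
    for N in (2, 5, 10):
        vals = [fixation_probability(1.0, rho, N) for rho in np.linspace(0.1, 10, 50)]
        assert all(a > b for a, b in zip(vals[:-1], vals[1:]))


def test_relative_fitness_zero_at_equality(neutral_kernels):
    assert relative_fitness(neutral_kernels, 0.5, 0.3, 0.3) == 0.0


@settings(deadline=None, max_examples=60)
@given(
    x=st.floats(min_value=0.0, max_value=1.0),
    y=st.floats(min_value=0.0, max_value=1.0),
)
def test_relative_fitness_antisymmetry(x, y):
    kern = preset_kernels("directional_1d", N=5, s=0.8)
    assert relative_fitness(kern, 0.5, y, x) == -relative_fitness(kern, 0.5, x, y)


def test_relative_fitness_directional_closed_form():
    # c = exp(s (y - x)) gives Fit(y, x) = 2 s (y - x)
    kern = preset_kernels("directional_1d", N=5, s=0.5)
    assert relative_fitness(kern, 0.5, 0.9, 0.4) == pytest.approx(2 * 0.5 * 0.5, rel=1e-12)


def test_relative_fitness_rejects_zero_rate():
    kern = ModelKernels(N=3, d=1, c=lambda r, x, y: 0.0, theta=lambda r, x: 0.0, lam=lambda r, x, r2, y: 0.0, c_bar=1.0)
    with pytest.raises(ValueError):
        relative_fitness(kern, 0.5, 0.1, 0.2)


def test_selection_gradient_neutral_is_zero(neutral_kernels):
    assert selection_gradient(neutral_kernels, 0.5, 0.4) == pytest.approx(np.zeros(1), abs=1e-10)


def test_selection_gradient_stabilizing_closed_form():
    # Fit(y, x) = s(|x - x0|^2 - |y - x0|^2): gradient at x is -2 s (x - x0)
    kern = preset_kernels("gaussian_stabilizing", N=5, s=1.5, x0=0.2)
    g = selection_gradient(kern, 0.5, 0.7)
    assert g[0] == pytest.approx(-2 * 1.5 * 0.5, rel=1e-6)


@pytest.mark.parametrize("N", [2, 5, 10])
@pytest.mark.parametrize(
    "name, params, x",
    [
        ("directional_1d", dict(s=0.7), 0.4),
        ("gaussian_stabilizing", dict(s=1.2, x0=0.1), 0.6),
        ("neutral", dict(), 0.3),
    ],
)
def test_fixation_gradient_identity(name, params, x, N):
    """grad_y alpha(x, x) = (N-1)/(2N) grad_y Fit(x, x) up to O(h^2)."""
    kern = preset_kernels(name, N=N, **params)
    ga = fixation_gradient(kern, 0.5, x)
    gf = selection_gradient(kern, 0.5, x)
    assert ga == pytest.approx((N - 1) / (2 * N) * gf, abs=1e-6)


def test_mutation_covariance_presets_and_factor(rng):
    kern = preset_kernels("neutral", N=5, d=1)
    Sigma, sigma = mutation_covariance(kern, 0.5, 0.0)
    assert Sigma == pytest.approx(np.eye(1))
    assert sigma @ sigma.T == pytest.approx(Sigma, abs=1e-12)


def test_mutation_covariance_uniform_steps_monte_carlo():
    a = 1.5
    kern = ModelKernels(
        N=5, d=1,
        c=lambda r, x, y: 1.0,
        theta=lambda r, x: 1.0,
        lam=lambda r, x, r2, y: 0.0,
        m_sampler=lambda g, r, x: g.uniform(-a, a, size=1),
        c_bar=1.0, theta_bar=1.0, lam_bar=0.0,
    )
    n_mc = 20000
    Sigma, sigma = mutation_covariance(kern, 0.5, 0.0, n_mc=n_mc, rng=7)
    true = a**2 / 3
    # var of the MC variance estimate for U(-a,a): (E h^4 - (E h^2)^2)/n
    se = np.sqrt((a**4 / 5 - true**2) / n_mc)
    assert abs(Sigma[0, 0] - true) < 3 * se
    assert sigma @ sigma.T == pytest.approx(Sigma, abs=1e-12)


def test_mutation_covariance_factor_contract_random_spd(rng):
    X = rng.standard_normal((3, 3))
    target = X @ X.T
    kern = ModelKernels(
        N=2, d=3,
        c=lambda r, x, y: 1.0,
        theta=lambda r, x: 1.0,
        lam=lambda r, x, r2, y: 0.0,
        Sigma_exact=lambda r, x: target,
        c_bar=1.0, theta_bar=1.0, lam_bar=0.0,
    )
    Sigma, sigma = mutation_covariance(kern, 0.5, np.zeros(3))
    assert sigma @ sigma.T == pytest.approx(Sigma, abs=1e-12)


def test_bound_violation_is_an_error():
    kern = ModelKernels(N=3, d=1, c=lambda r, x, y: 5.0, theta=lambda r, x: 0.0, lam=lambda r, x, r2, y: 0.0, c_bar=1.0)
    with pytest.raises(ValueError, match="violates"):
        kern.eval_c(0.5, 0.0, 1.0)


def test_unknown_preset_lists_available():
    with pytest.raises(KeyError, match="neutral"):
        preset_kernels("no_such_model")
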