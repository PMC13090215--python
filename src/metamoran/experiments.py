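"""Cross-level consistency experiments.

The point of the suite is that every scaling limit can be checked
numerically against the level below it.  Each function here runs one such
experiment end to end — simulate both levels, compare — and returns a small
dict of numbers (errors, z-scores, KS statistics, correlations).  They are
used by the test suite and by the reproduction script, and are callable
directly for exploration at other problem sizes.

All randomness flows through the ``seed`` argument; replicate seeds are
spawned from it deterministically.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import ks_2samp

from .canonical import (
    CanonicalConfig,
    EnvironmentEnsemble,
    drift_diffusion_coeffs,
    rescaled_small_mutation_kernels,
    simulate_canonical_homogeneous,
    simulate_environment,
    simulate_tagged,
)
from .kernels import (
    fixation_gradient,
    fixation_oracle,
    fixation_probability,
    preset_kernels,
    selection_gradient,
    two_trait_kernels,
)
from .meanfield import chaos_diagnostics, simulate_mckean_vlasov
from .micro import MicroConfig, MicroState, simulate_micro, substitution_counts
from .replicator import (
    build_interaction_matrix,
    exclusion_winner,
    interior_equilibrium,
    solve_replicator,
    solve_spatial_weights,
)
from .tss import TSSState, simulate_tss

__all__ = [
    "fixation_agreement",
    "neutral_identity",
    "gradient_identity",
    "micro_vs_tss",
    "chaos_decay",
    "replicator_exclusion",
    "replicator_cycling",
    "spatial_reduction",
    "canonical_variance",
    "mv_consistency",
    "small_mutation_trend",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def fixation_agreement(n_rho: int = 20, N_values=range(1, 11)) -> dict:
    """Closed-form fixation probability vs birth-death linear solve.

    Evaluates both on a (rho, N) grid (rho log-spaced in [0.1, 10]) and
    reports the worst absolute discrepancy and the grid size.
    """
    rhos = np.logspace(-1, 1, n_rho)
    max_diff = 0.0
    count = 0
    for rho in rhos:
        for N in N_values:
            a = fixation_probability(1.0, rho, N)
            b = fixation_oracle(1.0, rho, N)
            max_diff = max(max_diff, abs(a - b))
            count += 1
    return {"max_abs_diff": max_diff, "n_grid": count}


def neutral_identity(seed: int = 0, K: int = 100, N: int = 3, theta: float = 1.0, t_end: float = 50.0) -> dict:
    """Neutral identities: alpha = 1/N and substitution rate = theta.

    Under neutral resampling the fixation probability is exactly ``1/N``,
    so the mutation-fixation intensity ``N theta alpha`` collapses to
    ``theta`` per patch: total substitutions over [0, T] are Poisson with
    mean ``K theta T``.  Reports the exact alpha error and the z-score of
    the observed substitution count.
    """
    alpha_err = abs(fixation_probability(2.7, 2.7, N) - 1.0 / N)
    kern = preset_kernels("neutral", N=N, theta0=theta, lam0=0.0)
    traj = simulate_tss(TSSState(np.zeros((K, 1))), kern, t_end, seed=seed)
    observed = traj.n_events
    expected = K * theta * t_end
    z = (observed - expected) / np.sqrt(expected)
    return {
        "alpha_error": alpha_err,
        "observed_substitutions": observed,
        "expected_substitutions": expected,
        "rate_z": float(z),
        "observed_rate_per_patch": observed / (K * t_end),
    }


def gradient_identity(N_values=(2, 5, 10), h_fd: float = 1e-5) -> dict:
    """Fixation-gradient identity across selective presets and deme sizes.

    Checks ``grad_y alpha(r, x, x) = (N-1)/(2N) grad_y Fit(r, x, x)`` by
    central finite differences for three preset resampling kernels; the
    residual is O(h_fd^2) truncation plus round-off.
    """
    cases = [
        ("directional_1d", dict(s=0.7), 0.4),
        ("gaussian_stabilizing", dict(s=1.2, x0=0.1), 0.6),
        ("neutral", dict(), 0.3),
    ]
    max_err = 0.0
    for name, params, x in cases:
        for N in N_values:
            kern = preset_kernels(name, N=N, **params)
            ga = fixation_gradient(kern, 0.5, x, h_fd=h_fd)
            gf = selection_gradient(kern, 0.5, x, h_fd=h_fd)
            max_err = max(max_err, float(np.max(np.abs(ga - (N - 1) / (2 * N) * gf))))
    return {"max_abs_err": max_err, "n_cases": len(cases) * len(tuple(N_values))}


def micro_vs_tss(
    seed: int = 0,
    n_rep: int = 1000,
    K: int = 5,
    N: int = 5,
    gamma: float = 1e-3,
    t_tss: float = 0.5,
    theta: float = 1.0,
    lam: float = 0.4,
) -> dict:
    """Microscopic metapopulation vs substitution-sequence limit.

    Runs the exact Gillespie model at small gamma over natural time
    ``t_tss / gamma`` and the substitution-sequence simulator over
    ``t_tss``, both from the same monomorphic two-trait start with
    selection, and compares mean per-patch dominant-trait substitution
    counts by a two-sample z-test.
    """
    kern = two_trait_kernels(N=N, c_ab=2.0, c_ba=1.0, theta0=theta, lam0=lam)
    seeds = _child_seeds(seed, 2 * n_rep)
    micro_counts = np.zeros(n_rep)
    for i in range(n_rep):
        st = MicroState.monomorphic(K, N, 0.0)
        cfg = MicroConfig(kernels=kern, K=K, gamma=gamma, t_end=t_tss / gamma, seed=int(seeds[i]))
        micro_counts[i] = substitution_counts(simulate_micro(cfg, st)).sum()
    tss_counts = np.zeros(n_rep)
    for i in range(n_rep):
        traj = simulate_tss(TSSState(np.zeros((K, 1))), kern, t_tss, seed=int(seeds[n_rep + i]))
        tss_counts[i] = traj.substitution_counts().sum()
    m1, m2 = micro_counts.mean() / K, tss_counts.mean() / K
    se = np.sqrt(micro_counts.var(ddof=1) / n_rep + tss_counts.var(ddof=1) / n_rep) / K
    return {
        "micro_mean_per_patch": float(m1),
        "tss_mean_per_patch": float(m2),
        "z": float((m1 - m2) / se),
        "n_replicates": n_rep,
    }


def chaos_decay(
    seed: int = 0,
    K_values=(20, 50, 200),
    n_rep=(400, 300, 200),
    M: int = 2000,
    t_end: float = 1.5,
    n_tagged: int = 8,
) -> dict:
    """Propagation of chaos: tagged-patch decorrelation and MV marginal.

    Homogeneous continuous-trait substitution sequences at growing patch
    counts K; across replicates, the pairwise correlation of a bounded
    statistic (tanh of the trait) of tagged patches should shrink toward
    the null band, and the largest-K tagged marginal should be
    statistically indistinguishable from an M-particle McKean-Vlasov
    marginal (two-sample KS).
    """
    kern = preset_kernels("neutral", N=3, theta0=0.5, lam0=1.0, mut_scale=1.0)
    seed_pool = iter(_child_seeds(seed, 2 * sum(n_rep) + 1))
    stats = {}
    largest_marginal = None
    for K, reps in zip(K_values, n_rep):
        out = np.zeros((reps, n_tagged))
        marg = np.zeros(reps)
        for i in range(reps):
            s_init, s_run = int(next(seed_pool)), int(next(seed_pool))
            x0 = np.random.default_rng(s_init).standard_normal((K, 1))
            traj = simulate_tss(TSSState(x0), kern, t_end, seed=s_run)
            out[i] = np.tanh(traj.final_state.traits[:n_tagged, 0])
            marg[i] = traj.final_state.traits[0, 0]
        stats[K] = out
        largest_marginal = marg
    mv = simulate_mckean_vlasov(
        lambda rng, m: rng.standard_normal((m, 1)), kern, M, t_end, seed=int(next(seed_pool))
    )
    report = chaos_diagnostics(stats, marginal_samples=largest_marginal, reference_samples=mv.final_traits[:, 0])
    corr = {K: report["correlations"][K]["mean"] for K in K_values}
    return {
        "correlation_by_K": corr,
        "correlations_decreasing": bool(
            all(corr[a] > corr[b] for a, b in zip(K_values[:-1], K_values[1:]))
        ),
        "ks_statistic": report["ks"]["statistic"],
        "ks_pvalue": report["ks"]["pvalue"],
    }


def replicator_exclusion(t_end: float = 200.0) -> dict:
    """Competitive exclusion: the smallest trait takes over.

    Exclusion-regime interaction (a_ij = x^j - x^i) on traits
    {0.2, 0.5, 0.8} from uniform weights: total mass must stay at 1 and
    the smallest trait's mean weight must exceed 1 - 1e-3 by the horizon,
    with the competitor mass non-increasing along the way.
    """
    kern = preset_kernels("case1_exclusion", N=5)
    traits = [0.2, 0.5, 0.8]
    A = build_interaction_matrix(traits, kern)
    w0 = np.full(3, 1.0 / 3.0)
    times, W = solve_replicator(A, w0, t_end, t_eval=np.linspace(0, t_end, 2001))
    winner = exclusion_winner(A, w0)
    S = 1.0 - W[:, winner]
    return {
        "winner_index": winner,
        "winner_trait": traits[winner],
        "winner_final_weight": float(W[-1, winner]),
        "mass_drift": float(np.abs(W.sum(axis=1) - 1.0).max()),
        "competitor_mass_increase": float(np.max(np.diff(S))),
    }


def replicator_cycling(t_end: float = 100.0) -> dict:
    """Cycling regime: bounded oscillation around the interior equilibrium.

    Cycling interaction (G = 2 sin(2 pi (x - y))) on traits {0.2, 0.5, 0.8}:
    no strictly dominant row exists, an interior equilibrium w* does, and
    the zero-sum constant of motion ``sum_i w*_i log wbar_i`` must stay
    flat while the orbit keeps oscillating.
    """
    kern = preset_kernels("case2_cycling", N=5)
    traits = [0.2, 0.5, 0.8]
    A = build_interaction_matrix(traits, kern)
    w0 = np.full(3, 1.0 / 3.0)
    wstar = interior_equilibrium(A)
    times, W = solve_replicator(A, w0, t_end, t_eval=np.linspace(0, t_end, 4001))
    V = (wstar * np.log(W)).sum(axis=1)
    late = W[times >= t_end / 2, 0]
    return {
        "has_winner": exclusion_winner(A, w0) is not None,
        "equilibrium": wstar.tolist(),
        "invariant_drift": float(np.abs(V - V[0]).max()),
        "late_oscillation_range": float(late.max() - late.min()),
        "mass_drift": float(np.abs(W.sum(axis=1) - 1.0).max()),
    }


def spatial_reduction(m: int = 32, t_end: float = 20.0) -> dict:
    """Spatial weight field vs mean-weight replicator reduction.

    Integrates the migration-fixation weight system on an m-point midpoint
    grid with spatially varying initial weights under homogeneous kernels;
    the position-averaged trajectory must reproduce the replicator ODE.
    """
    kern = preset_kernels("case1_exclusion", N=5)
    traits = [0.2, 0.5, 0.8]
    rs = (np.arange(m) + 0.5) / m
    # spatially varying but column-stochastic initial profile
    w0_grid = np.vstack(
        [0.2 + 0.2 * np.sin(2 * np.pi * rs), 0.3 + 0.1 * np.cos(2 * np.pi * rs)]
    )
    w0_grid = np.vstack([w0_grid, 1.0 - w0_grid.sum(axis=0)])
    t_eval = np.linspace(0, t_end, 101)
    _, Ws = solve_spatial_weights(traits, w0_grid, kern, t_end, t_eval=t_eval)
    A = build_interaction_matrix(traits, kern)
    _, Wbar = solve_replicator(A, w0_grid.mean(axis=1), t_end, t_eval=t_eval)
    return {
        "max_abs_err": float(np.abs(Ws.mean(axis=2) - Wbar).max()),
        "grid_points": m,
        "local_mass_drift": float(np.abs(Ws.sum(axis=1) - 1.0).max()),
    }


def canonical_variance(seed: int = 0, M: int = 2000, t_end: float = 1.0, dt: float = 0.01, theta: float = 0.5) -> dict:
    """Diffusion-only closed form: Var(X_t) = theta Sigma t.

    Neutral resampling, no migration, constant mutation rate and unit step
    covariance: the canonical process is a Brownian motion with variance
    rate theta, so the ensemble variance at t must match theta * t within
    Monte-Carlo error (the sample variance of M Gaussians has standard
    error sqrt(2/(M-1)) * theta * t).  Also evaluates the advection at
    N = 1, which must vanish identically.
    """
    kern = preset_kernels("neutral", N=5, theta0=theta, lam0=0.0)
    xi0 = EnvironmentEnsemble(np.full(M, 0.5), np.zeros((M, 1)))
    env = simulate_environment(xi0, kern, t_end, dt=dt, seed=seed, record_times=[t_end])
    var = float(env.snapshots[-1].var(ddof=1))
    expected = theta * t_end
    se = np.sqrt(2.0 / (M - 1)) * expected
    drift1, _ = drift_diffusion_coeffs(preset_kernels("gaussian_stabilizing", N=1, s=2.0), 0.5, 0.9)
    return {
        "variance": var,
        "expected": expected,
        "z": float((var - expected) / se),
        "N1_drift_norm": float(np.linalg.norm(drift1)),
    }


def mv_consistency(
    seed: int = 0,
    M: int = 1500,
    n_tagged: int = 400,
    t_end: float = 1.0,
    dt: float = 0.01,
) -> dict:
    """Tagged jump-diffusion vs its own environment marginal (homogeneity).

    With homogeneous kernels and the tagged initial law equal to the
    environment's trait marginal, the tagged path at time t must be
    distributed like the environment ensemble's trait marginal; compared by
    a two-sample KS test.
    """
    kern = preset_kernels("gaussian_stabilizing", N=4, s=1.0, x0=0.0, theta0=1.0, lam0=0.5, box=(-4, 4))
    seeds = _child_seeds(seed, 3)
    rng = np.random.default_rng(int(seeds[0]))
    mu0 = lambda g, m: g.normal(0.5, 0.3, size=(m, 1))
    xi0 = EnvironmentEnsemble.sample(mu0, M, rng)
    env = simulate_environment(xi0, kern, t_end, dt=dt, seed=int(seeds[1]))
    cfg = CanonicalConfig(kernels=kern, z=0.5, M=M, dt=dt, t_end=t_end, seed=int(seeds[2]))
    x0 = np.random.default_rng(int(seeds[2]) + 1).normal(0.5, 0.3, size=(n_tagged, 1))
    tagged = simulate_tagged(x0, cfg, env)
    ks = ks_2samp(tagged.paths[-1][:, 0], env.snapshots[-1][:, 0])
    return {"ks_statistic": float(ks.statistic), "ks_pvalue": float(ks.pvalue)}


def small_mutation_trend(
    seed: int = 0,
    eps_values=(0.5, 0.25, 0.1),
    M: int = 400,
    M_ref: int = 1500,
    n_rep: int = 4,
    t_end: float = 0.3,
) -> dict:
    """Substitution sequences approach the canonical jump-diffusion.

    Runs the McKean-Vlasov substitution-sequence level with mutation steps
    scaled by eps and migration by eps^2, to natural time t/eps^2, and
    compares its trait marginal (two-sample KS, averaged over ``n_rep``
    replicates to tame sampling noise) with the canonical jump-diffusion
    ensemble at time t; the distance should shrink as eps decreases.
    Reduced scale: the check is of the trend, not the limit.
    """
    base = preset_kernels("gaussian_stabilizing", N=3, s=1.0, x0=0.0, theta0=1.0, lam0=0.3, box=(-4, 4))
    rng = np.random.default_rng(seed)
    mu0 = lambda g, m: g.normal(0.8, 0.2, size=(m, 1))
    can = simulate_canonical_homogeneous(
        mu0, base, M_ref, t_end, dt=0.01, seed=int(rng.integers(2**31)), record_times=[t_end]
    )
    ref = can.snapshots[-1][:, 0]
    ks_by_eps = {}
    for eps in eps_values:
        ke = rescaled_small_mutation_kernels(base, eps)
        ks_list = [
            ks_2samp(
                simulate_mckean_vlasov(mu0, ke, M, t_end / eps**2, seed=int(rng.integers(2**31))).final_traits[:, 0],
                ref,
            ).statistic
            for _ in range(n_rep)
        ]
        ks_by_eps[eps] = float(np.mean(ks_list))
    vals = [ks_by_eps[e] for e in eps_values]
    return {"ks_by_eps": ks_by_eps, "decreasing": bool(all(a > b for a, b in zip(vals[:-1], vals[1:])))}
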