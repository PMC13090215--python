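"""Large-K limits: deterministic atomic-measure flow and the McKean-Vlasov
interacting-particle system.

As the number of patches grows, the empirical trait distribution
``nu_t(dr, dx)`` over position x trait space becomes deterministic and obeys
a closed weak evolution equation with two conservative jump-rate terms:
mutation-fixation (``N theta alpha Q``) and migration-fixation
(``N^2 lam alpha`` against ``nu_t`` itself).  For finitely supported
measures (finite trait set, discrete mutation law) the equation closes into
an ODE on atom weights, solved here exactly; general measures are handled by
the particle system instead.

Under mean-field dispersal the tagged-patch trait is a McKean-Vlasov
pure-jump process: its migration-fixation rate integrates against its own
time-marginal law ``mu_t``.  It is approximated by ``M`` interacting
particles whose empirical law stands in for ``mu_t``; jump proposals are
thinned against the constant kernel bounds, so event times are exact.
Finitely many tagged patches decorrelate as the system grows (propagation of
chaos); :func:`chaos_diagnostics` measures that decay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import ks_2samp

from .kernels import ModelKernels, as_trait, trait_key

__all__ = [
    "AtomicMeasure",
    "MeasureTrajectory",
    "ParticleTrajectory",
    "evolve_atomic_measure",
    "simulate_mckean_vlasov",
    "chaos_diagnostics",
]


@dataclass
class AtomicMeasure:
    """Weighted atoms on [0, 1] x R^d representing a probability measure."""

    positions: np.ndarray  # (n,)
    traits: np.ndarray     # (n, d)
    weights: np.ndarray    # (n,)

    def __post_init__(self):
        self.positions = np.atleast_1d(np.asarray(self.positions, dtype=float))
        self.traits = np.atleast_2d(np.asarray(self.traits, dtype=float))
        if self.traits.shape[0] != self.positions.shape[0] and self.traits.shape[1] == self.positions.shape[0]:
            self.traits = self.traits.T
        self.weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        if not (len(self.positions) == len(self.weights) == self.traits.shape[0]):
            raise ValueError("positions, traits and weights must have matching lengths")
        if np.any(self.weights < 0):
            raise ValueError("atom weights must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.weights)

    @property
    def total_mass(self) -> float:
        return float(np.sum(self.weights))

    def trait_marginal(self) -> tuple[np.ndarray, np.ndarray]:
        """Unique traits and their aggregated weights (integrated over r)."""
        keys = {}
        for x, w in zip(self.traits, self.weights):
            keys.setdefault(trait_key(x), [x, 0.0])[1] += w
        traits = np.array([v[0] for v in keys.values()])
        weights = np.array([v[1] for v in keys.values()])
        return traits, weights

    @classmethod
    def from_grid(cls, rs, traits, W) -> "AtomicMeasure":
        """Build from a position grid ``rs`` (p,), trait set (n, d) and
        weight matrix ``W`` (p, n); grid weights are divided by p so that a
        row-stochastic W yields total mass 1 (midpoint quadrature)."""
        rs = np.asarray(rs, dtype=float)
        traits = np.atleast_2d(np.asarray(traits, dtype=float))
        W = np.asarray(W, dtype=float)
        p, n = W.shape
        pos = np.repeat(rs, n)
        tr = np.tile(traits, (p, 1))
        return cls(pos, tr, W.reshape(-1) / p)


@dataclass
class MeasureTrajectory:
    times: np.ndarray
    positions: np.ndarray   # (p,)
    traits: np.ndarray      # (n, d)
    weights: np.ndarray     # (T, p, n) atom weights (summing to 1 over p*n)

    def measure_at(self, idx: int) -> AtomicMeasure:
        p, n = self.weights.shape[1:]
        pos = np.repeat(self.positions, n)
        tr = np.tile(self.traits, (p, 1))
        return AtomicMeasure(pos, tr, self.weights[idx].reshape(-1))

    def mass(self) -> np.ndarray:
        return self.weights.sum(axis=(1, 2))

    def trait_mean_weights(self) -> np.ndarray:
        """(T, n) weights of each trait integrated over positions."""
        return self.weights.sum(axis=1)


def _grid_form(nu0: AtomicMeasure):
    """Decompose an atomic measure into (positions, trait set, weight matrix)."""
    pos_keys, trait_keys = [], []
    for r in nu0.positions:
        if r not in pos_keys:
            pos_keys.append(r)
    for x in nu0.traits:
        k = trait_key(x)
        if k not in trait_keys:
            trait_keys.append(k)
    rs = np.array(pos_keys)
    xs = np.array([np.array(k) for k in trait_keys])
    W = np.zeros((len(rs), len(xs)))
    pos_idx = {r: i for i, r in enumerate(pos_keys)}
    tr_idx = {k: i for i, k in enumerate(trait_keys)}
    for r, x, w in zip(nu0.positions, nu0.traits, nu0.weights):
        W[pos_idx[r], tr_idx[trait_key(x)]] += w
    return rs, xs, W


def evolve_atomic_measure(
    nu0: AtomicMeasure,
    kernels: ModelKernels,
    t_end: float,
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> MeasureTrajectory:
    """Deterministic evolution of a finitely supported measure.

    Plugs the atomic ansatz into the weak limit equation: mass flows between
    atoms at mutation-fixation rate ``N theta(r, x) alpha(r, y, x) Q(x -> y)``
    (same position) and migration-fixation rate
    ``N^2 alpha(r, y, x) sum_atoms lam((r, x), (r', y)) w``, giving a closed,
    conservative weight ODE integrated with adaptive explicit Runge-Kutta.
    Mass is conserved by the vector field; the solver's drift is monitored by
    tests, never renormalised away.

    Requires a finite trait support: a discrete mutation law (``Q_support``)
    or mutation disabled.  Continuous mutation kernels are the particle
    simulator's job (:func:`simulate_mckean_vlasov`).
    """
    mutation_on = kernels.theta_bar > 0
    if mutation_on and kernels.Q_support is None:
        raise ValueError(
            "evolve_atomic_measure needs a finite-support mutation law (Q_support); "
            "use simulate_mckean_vlasov for continuous mutation kernels"
        )
    rs, xs, W0 = _grid_form(nu0)

    # close the trait set under the discrete mutation law
    if mutation_on:
        seen = {trait_key(x) for x in xs}
        frontier = list(xs)
        while frontier:
            x = frontier.pop()
            for r in rs:
                for y, _ in kernels.Q_support(r, x):
                    yk = trait_key(y)
                    if yk not in seen:
                        if len(seen) >= 10000:
                            raise ValueError("mutation support closure exceeds 10000 traits")
                        seen.add(yk)
                        frontier.append(as_trait(y, kernels.d))
        if len(seen) > xs.shape[0]:
            extra = [np.array(k) for k in seen - {trait_key(x) for x in xs}]
            xs = np.vstack([xs, extra])
            W0 = np.hstack([W0, np.zeros((len(rs), len(extra)))])

    p, n = W0.shape
    N = kernels.N

    # alpha[k, i, j]: invader x_j against resident x_i at position r_k
    alpha = np.empty((p, n, n))
    for k, r in enumerate(rs):
        for i in range(n):
            for j in range(n):
                alpha[k, i, j] = kernels.invasion_probability(r, xs[j], xs[i]) if i != j else 0.0
    # lam4[k, i, l, j]: resident (r_k, x_i), incoming (r_l, x_j)
    lam4 = np.empty((p, n, p, n))
    for k, r in enumerate(rs):
        for i in range(n):
            for l, r2 in enumerate(rs):
                for j in range(n):
                    lam4[k, i, l, j] = kernels.eval_lam(r, xs[i], r2, xs[j]) if i != j else 0.0

    # mut[k, i, j]: per-unit-mass flow (r_k, x_i) -> (r_k, x_j) by mutation-fixation
    mut = np.zeros((p, n, n))
    if mutation_on:
        tr_idx = {trait_key(x): i for i, x in enumerate(xs)}
        for k, r in enumerate(rs):
            for i in range(n):
                th = kernels.eval_theta(r, xs[i])
                if th == 0.0:
                    continue
                for y, prob in kernels.Q_support(r, xs[i]):
                    j = tr_idx[trait_key(y)]
                    if j != i:
                        mut[k, i, j] += N * th * alpha[k, i, j] * prob

    def rhs(t, w_flat):
        W = w_flat.reshape(p, n)
        # Lam[k, i, j] = sum_l lam4[k, i, l, j] W[l, j]: migrant supply of
        # trait j available to the resident atom (k, i)
        Lam = np.einsum("kilj,lj->kij", lam4, W)
        out = N**2 * W * np.einsum("kij,kij->ki", alpha, Lam)
        # inflow to (k, i): resident atoms (k, j) adopting trait i
        inc = N**2 * np.einsum("kj,kji,kji->ki", W, alpha, Lam)
        m_out = W * mut.sum(axis=2)
        m_in = np.einsum("kj,kji->ki", W, mut)
        return (inc - out + m_in - m_out).reshape(-1)

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 101)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (0.0, t_end), W0.reshape(-1), t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise RuntimeError(f"weight ODE integration failed: {sol.message}")
    weights = sol.y.T.reshape(len(sol.t), p, n)
    return MeasureTrajectory(times=sol.t, positions=rs, traits=xs, weights=weights)


@dataclass
class ParticleTrajectory:
    record_times: np.ndarray
    snapshots: np.ndarray        # (T, M, d)
    final_traits: np.ndarray     # (M, d)
    jump_counts: np.ndarray      # (M,) accepted jumps per particle
    proposal_counts: dict = field(default_factory=dict)
    acceptance_counts: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.final_traits.shape[0]


def simulate_mckean_vlasov(
    mu0,
    kernels: ModelKernels,
    M: int,
    t_end: float,
    seed: int | None = None,
    record_times: Optional[Sequence[float]] = None,
    max_proposals: int = 50_000_000,
) -> ParticleTrajectory:
    """Interacting-particle approximation of the McKean-Vlasov jump process.

    Homogeneous kernels only.  Each particle jumps by mutation-fixation
    (thinned at rate ``N theta_bar``) and by migration-fixation: proposals at
    rate ``N^2 lam_bar``, a partner drawn uniformly among the other ``M - 1``
    particles, accepted with ``lam(x, y) alpha(y, x) / lam_bar``; on
    acceptance the particle copies the partner's trait.  Self-interaction is
    excluded, mirroring the pre-limit sum over distinct patches.

    ``mu0`` is either an ``(M, d)`` array of initial traits or a callable
    ``mu0(rng, M) -> (M, d)``.
    """
    if not kernels.homogeneous:
        raise ValueError("the McKean-Vlasov simulator requires homogeneous kernels")
    if M < 2:
        raise ValueError("M must be >= 2")
    rng = np.random.default_rng(seed)
    if callable(mu0):
        traits = np.atleast_2d(np.asarray(mu0(rng, M), dtype=float))
    else:
        traits = np.atleast_2d(np.asarray(mu0, dtype=float)).copy()
    if traits.shape != (M, kernels.d):
        raise ValueError(f"initial traits have shape {traits.shape}, expected {(M, kernels.d)}")

    N = kernels.N
    mut_bound = N * kernels.theta_bar
    mig_bound = N**2 * kernels.lam_bar
    if mut_bound > 0 and kernels.Q_sampler is None:
        raise ValueError("kernels.Q_sampler required when mutation is active")
    total_rate = M * (mut_bound + mig_bound)

    rec = None if record_times is None else np.asarray(record_times, dtype=float)
    snaps = np.empty((0, M, kernels.d)) if rec is None else np.empty((len(rec), M, kernels.d))
    next_rec = 0
    jump_counts = np.zeros(M, dtype=int)
    prop = {"mutation": 0, "migration": 0}
    acc = {"mutation": 0, "migration": 0}
    r0 = 0.5  # positions are immaterial under homogeneity

    def snapshot_up_to(t):
        nonlocal next_rec
        while rec is not None and next_rec < len(rec) and rec[next_rec] <= t:
            snaps[next_rec] = traits
            next_rec += 1

    t = 0.0
    if total_rate > 0:
        for _ in range(max_proposals):
            t += rng.exponential(1.0 / total_rate)
            if t >= t_end:
                break
            snapshot_up_to(t)
            i = int(rng.integers(M))
            x = traits[i]
            if rng.uniform(0.0, mut_bound + mig_bound) < mut_bound:
                prop["mutation"] += 1
                y = as_trait(kernels.Q_sampler(rng, r0, x), kernels.d)
                accept = (
                    kernels.eval_theta(r0, x) / kernels.theta_bar
                    * kernels.invasion_probability(r0, y, x)
                )
                if accept > 1.0 + 1e-12:
                    raise RuntimeError(f"thinning bound violated: acceptance {accept} > 1")
                if rng.random() < accept:
                    acc["mutation"] += 1
                    traits[i] = y
                    jump_counts[i] += 1
            else:
                prop["migration"] += 1
                j = int(rng.integers(M - 1))
                if j >= i:
                    j += 1
                y = traits[j]
                if np.array_equal(y, x):
                    continue
                accept = (
                    kernels.eval_lam(r0, x, r0, y) / kernels.lam_bar
                    * kernels.invasion_probability(r0, y, x)
                )
                if accept > 1.0 + 1e-12:
                    raise RuntimeError(f"thinning bound violated: acceptance {accept} > 1")
                if rng.random() < accept:
                    acc["migration"] += 1
                    traits[i] = y.copy()
                    jump_counts[i] += 1
        else:
            raise RuntimeError("max_proposals exceeded before reaching t_end")

    snapshot_up_to(np.inf)
    return ParticleTrajectory(
        record_times=rec if rec is not None else np.array([]),
        snapshots=snaps,
        final_traits=traits,
        jump_counts=jump_counts,
        proposal_counts=prop,
        acceptance_counts=acc,
    )


def chaos_diagnostics(
    tagged_stats: dict,
    marginal_samples: Optional[np.ndarray] = None,
    reference_samples: Optional[np.ndarray] = None,
) -> dict:
    """Correlation-decay and KS-distance report for propagation of chaos.

    ``tagged_stats`` maps a system size (K or M) to an
    ``(n_replicates, n_units)`` array of a bounded statistic of each tagged
    unit at a fixed time.  For each size the mean pairwise Pearson
    correlation over unit pairs is reported (with its average magnitude);
    asymptotic independence shows as correlations shrinking toward the null
    band as the size grows.  When ``marginal_samples`` and
    ``reference_samples`` are given, a two-sample Kolmogorov-Smirnov
    comparison of the tagged marginal against the reference (e.g. the
    McKean-Vlasov particle marginal) is included.
    """
    report = {"correlations": {}}
    for size, stats in tagged_stats.items():
        stats = np.asarray(stats, dtype=float)
        if stats.ndim != 2 or stats.shape[1] < 2:
            raise ValueError("need >= 2 tagged units per system size")
        n_rep, n_units = stats.shape
        if n_rep < 100:
            raise ValueError("need >= 100 replicates for correlation estimates")
        corrs = []
        for a in range(n_units):
            for b in range(a + 1, n_units):
                sa, sb = stats[:, a], stats[:, b]
                if np.std(sa) == 0 or np.std(sb) == 0:
                    corrs.append(0.0)
                else:
                    corrs.append(float(np.corrcoef(sa, sb)[0, 1]))
        corrs = np.array(corrs)
        report["correlations"][size] = {
            "mean": float(corrs.mean()),
            "mean_abs": float(np.abs(corrs).mean()),
            "n_pairs": len(corrs),
            "n_replicates": n_rep,
            "null_band": 3.0 / np.sqrt(n_rep),
        }
    if marginal_samples is not None and reference_samples is not None:
        ks = ks_2samp(np.ravel(marginal_samples), np.ravel(reference_samples))
        report["ks"] = {"statistic": float(ks.statistic), "pvalue": float(ks.pvalue)}
    return report
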