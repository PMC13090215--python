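"""Coupled trait substitution sequences: the rare-mutation/migration limit.

In the limit of rare mutation and migration (time rescaled by the scaling
parameter), each patch is monomorphic at all times and the metapopulation is
a pure-jump Markov chain on the ``K`` dominant traits ``x^1, ..., x^K``:

* substitution in patch ``l``: the dominant trait jumps from ``x`` to a
  mutant ``y ~ Q(l/K, x, dy)`` at rate ``N theta(l/K, x) alpha(l/K, y, x)``
  (a mutation followed by fixation);
* migration-fixation: patch ``l`` adopts the dominant trait of patch ``l'``
  at rate ``(N^2 / K) lam((l/K, x^l), (l'/K, x^l')) alpha(l/K, x^l', x^l)``.

Simulation is by exact thinning: proposals arrive at constant bound rates
(``N theta_bar`` per patch for mutation, ``N^2 lam_bar (K-1)/K`` per patch
for migration with the source patch uniform on the other ``K - 1``) and are
accepted with probability ``(rate / bound) * alpha``, which is a valid
acceptance probability because ``alpha`` is itself a probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .kernels import ModelKernels, as_trait, trait_key

__all__ = ["TSSState", "TSSTrajectory", "tss_rates", "simulate_tss"]


@dataclass
class TSSState:
    """Dominant traits of the K patches; patch ``l`` sits at position ``(l+1)/K``."""

    traits: np.ndarray  # (K, d)

    def __post_init__(self):
        self.traits = np.atleast_2d(np.asarray(self.traits, dtype=float))

    @property
    def K(self) -> int:
        return self.traits.shape[0]

    @property
    def d(self) -> int:
        return self.traits.shape[1]

    def position(self, patch: int) -> float:
        return (patch + 1) / self.K

    @classmethod
    def from_values(cls, values) -> "TSSState":
        return cls(np.array([as_trait(v) for v in values]))


@dataclass
class TSSTrajectory:
    t_end: float
    state0: TSSState
    times: list = field(default_factory=list)
    events: list = field(default_factory=list)  # (t, channel, patch, old, new, src_patch)
    record_times: Optional[np.ndarray] = None
    snapshots: Optional[np.ndarray] = None      # (len(record_times), K, d)
    final_state: Optional[TSSState] = None
    proposal_counts: dict = field(default_factory=dict)
    acceptance_counts: dict = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    def substitution_counts(self) -> np.ndarray:
        counts = np.zeros(self.state0.K, dtype=int)
        for (_, _, l, _, _, _) in self.events:
            counts[l] += 1
        return counts


def tss_rates(state: TSSState, kernels: ModelKernels) -> dict:
    """Per-patch substitution and migration-fixation rate summaries.

    ``mutation_fixation[l]`` is the total mutation-fixation intensity of
    patch ``l``: the exact sum ``N theta sum_y alpha(y, x) Q({y})`` for a
    discrete mutation law (``Q_support`` available), otherwise the thinning
    upper bound ``N theta`` (``exact_mutation`` is False in that case).
    ``migration_fixation[l, l2]`` is the rate at which patch ``l`` adopts the
    dominant trait of patch ``l2``; it is zero on the diagonal and for
    identical traits (the jump would be a no-op).
    """
    K, N = state.K, kernels.N
    mut = np.zeros(K)
    exact = kernels.Q_support is not None
    for l in range(K):
        r = state.position(l)
        x = state.traits[l]
        th = kernels.eval_theta(r, x)
        if th == 0.0:
            continue
        if exact:
            total = 0.0
            for y, prob in kernels.Q_support(r, x):
                total += kernels.invasion_probability(r, as_trait(y, kernels.d), x) * prob
            mut[l] = N * th * total
        else:
            mut[l] = N * th  # upper bound: alpha <= 1
    mig = np.zeros((K, K))
    if kernels.lam_bar > 0 and K > 1:
        for l in range(K):
            r = state.position(l)
            x = state.traits[l]
            for l2 in range(K):
                if l2 == l or np.array_equal(state.traits[l2], x):
                    continue
                r2 = state.position(l2)
                y = state.traits[l2]
                mig[l, l2] = (
                    N**2 / K
                    * kernels.eval_lam(r, x, r2, y)
                    * kernels.invasion_probability(r, y, x)
                )
    return {"mutation_fixation": mut, "exact_mutation": exact, "migration_fixation": mig}


def simulate_tss(
    state0: TSSState,
    kernels: ModelKernels,
    t_end: float,
    seed: int | None = None,
    record_times: Optional[Sequence[float]] = None,
    max_proposals: int = 20_000_000,
) -> TSSTrajectory:
    """Exact thinning simulation of the coupled substitution sequences.

    Accepted events overwrite the patch's dominant trait; the trajectory
    records every accepted event plus (optionally) full-state snapshots at
    ``record_times``.  Proposal and acceptance counts per channel are kept so
    thinning health can be audited.
    """
    rng = np.random.default_rng(seed)
    K, N = state0.K, kernels.N
    traits = state0.traits.copy()
    mut_bound = N * kernels.theta_bar
    mig_bound = N**2 * kernels.lam_bar * (K - 1) / K if K > 1 else 0.0
    if mut_bound > 0 and kernels.Q_sampler is None:
        raise ValueError("kernels.Q_sampler required when mutation is active")
    total_rate = K * (mut_bound + mig_bound)

    rec = None if record_times is None else np.asarray(record_times, dtype=float)
    snaps = None if rec is None else np.empty((len(rec), K, state0.d))
    next_rec = 0

    traj = TSSTrajectory(t_end=t_end, state0=TSSState(state0.traits.copy()))
    traj.proposal_counts = {"mutation": 0, "migration": 0}
    traj.acceptance_counts = {"mutation": 0, "migration": 0}

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
            l = int(rng.integers(K))
            r = (l + 1) / K
            x = traits[l]
            if rng.uniform(0.0, mut_bound + mig_bound) < mut_bound:
                traj.proposal_counts["mutation"] += 1
                y = as_trait(kernels.Q_sampler(rng, r, x), kernels.d)
                accept = (
                    kernels.eval_theta(r, x) / kernels.theta_bar
                    * kernels.invasion_probability(r, y, x)
                )
                if accept > 1.0 + 1e-12:
                    raise RuntimeError(f"thinning bound violated: acceptance {accept} > 1")
                if rng.random() < accept:
                    traj.acceptance_counts["mutation"] += 1
                    traj.times.append(t)
                    traj.events.append((t, "substitution", l, x.copy(), y.copy(), -1))
                    traits[l] = y
            else:
                traj.proposal_counts["migration"] += 1
                l2 = int(rng.integers(K - 1))
                if l2 >= l:
                    l2 += 1
                y = traits[l2]
                if np.array_equal(y, x):
                    continue  # no-op jump
                r2 = (l2 + 1) / K
                accept = (
                    kernels.eval_lam(r, x, r2, y) / kernels.lam_bar
                    * kernels.invasion_probability(r, y, x)
                )
                if accept > 1.0 + 1e-12:
                    raise RuntimeError(f"thinning bound violated: acceptance {accept} > 1")
                if rng.random() < accept:
                    traj.acceptance_counts["migration"] += 1
                    traj.times.append(t)
                    traj.events.append((t, "migration-fixation", l, x.copy(), y.copy(), l2))
                    traits[l] = y.copy()
        else:
            raise RuntimeError("max_proposals exceeded before reaching t_end")

    snapshot_up_to(np.inf)
    traj.record_times = rec
    traj.snapshots = snaps
    traj.final_state = TSSState(traits.copy())
    return traj
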