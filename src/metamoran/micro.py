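"""Exact Gillespie simulation of the K-deme Moran metapopulation.

Each of ``K`` patches at positions ``l/K`` holds exactly ``N`` individuals.
Three event channels act on the configuration: within-patch resampling at
pairwise rate ``c(l/K, x, y)`` (the ``x`` individual is replaced by a ``y``
copy), mutation at per-capita rate ``gamma * theta(l/K, x)`` with mutant law
``Q``, and migration at rate ``gamma / K * lam((l/K, x), (l'/K, y))`` per
ordered cross-patch pair (the ``x`` individual in patch ``l`` is replaced by
a copy of the ``y`` individual in patch ``l'``).

Events whose source and target carry bit-identical traits change nothing;
the simulator suppresses them (summing rates over ordered pairs with
*distinct* trait values only), which leaves the law of the trait
configuration unchanged while skipping the overwhelmingly dominant no-op
resampling activity of a near-monomorphic deme.  States are stored as
per-patch trait-count maps; traits are compared by exact bit equality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kernels import ModelKernels, as_trait, trait_key

__all__ = [
    "MicroConfig",
    "MicroState",
    "JumpTrajectory",
    "total_event_rate",
    "simulate_micro",
    "empirical_measure",
    "dominant_trait",
    "substitution_counts",
]


@dataclass
class MicroConfig:
    kernels: ModelKernels
    K: int
    gamma: float
    t_end: float
    seed: int | None = None
    max_events: int = 5_000_000

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")


@dataclass
class MicroState:
    """Per-patch multisets of N trait vectors, as trait-count maps."""

    K: int
    N: int
    counts: list  # list of dict[trait_key, int]
    traits: dict  # trait_key -> np.ndarray

    @classmethod
    def from_traits(cls, patch_traits, N: int | None = None) -> "MicroState":
        """Build from a list (per patch) of lists of trait values."""
        counts, registry = [], {}
        sizes = set()
        for patch in patch_traits:
            cmap: dict = {}
            n = 0
            for x in patch:
                xv = as_trait(x)
                k = trait_key(xv)
                registry.setdefault(k, xv)
                cmap[k] = cmap.get(k, 0) + 1
                n += 1
            sizes.add(n)
            counts.append(cmap)
        if len(sizes) != 1:
            raise ValueError("all patches must hold the same number of individuals")
        n = sizes.pop()
        if N is not None and N != n:
            raise ValueError(f"patches hold {n} individuals, expected N={N}")
        return cls(K=len(counts), N=n, counts=counts, traits=registry)

    @classmethod
    def monomorphic(cls, K: int, N: int, x) -> "MicroState":
        return cls.from_traits([[x] * N for _ in range(K)])

    def position(self, patch: int) -> float:
        return (patch + 1) / self.K

    def copy(self) -> "MicroState":
        return MicroState(self.K, self.N, [dict(c) for c in self.counts], dict(self.traits))

    def patch_size(self, patch: int) -> int:
        return sum(self.counts[patch].values())


@dataclass
class JumpTrajectory:
    """Piecewise-constant path of a pure-jump process (cadlag convention).

    ``events`` rows are ``(time, type, patch, from_key, to_key, src_patch)``;
    ``src_patch`` is -1 except for migration events.
    """

    t0: float
    t_end: float
    state0: MicroState
    times: list = field(default_factory=list)
    events: list = field(default_factory=list)
    final_state: Optional[MicroState] = None

    @property
    def n_events(self) -> int:
        return len(self.events)


class _RateTable:
    """Per-patch event rates with memoised kernel evaluations.

    Only state-changing events are tabulated: resampling and migration sums
    run over ordered pairs with distinct trait values.  After an event in
    patch ``l`` only the rows touching ``l`` are rebuilt.
    """

    def __init__(self, state: MicroState, config: MicroConfig):
        self.state = state
        self.cfg = config
        self.ker = config.kernels
        self._c_memo: dict = {}
        self._th_memo: dict = {}
        self._lam_memo: dict = {}
        K = state.K
        self.res = [None] * K   # list of (entries, total); entries = [(rate, xk, yk)]
        self.mut = [None] * K
        self.mig = [[None] * K for _ in range(K)]  # [target][source]
        for l in range(K):
            self._rebuild_local(l)
        for l in range(K):
            for l2 in range(K):
                if l2 != l:
                    self._rebuild_mig(l, l2)

    # memoised kernels -----------------------------------------------------
    def _c(self, r, xk, yk):
        key = (r, xk, yk)
        v = self._c_memo.get(key)
        if v is None:
            v = self.ker.eval_c(r, self.state.traits[xk], self.state.traits[yk])
            self._c_memo[key] = v
        return v

    def _th(self, r, xk):
        key = (r, xk)
        v = self._th_memo.get(key)
        if v is None:
            v = self.ker.eval_theta(r, self.state.traits[xk])
            self._th_memo[key] = v
        return v

    def _lam(self, r, xk, r2, yk):
        key = (r, xk, r2, yk)
        v = self._lam_memo.get(key)
        if v is None:
            v = self.ker.eval_lam(r, self.state.traits[xk], r2, self.state.traits[yk])
            self._lam_memo[key] = v
        return v

    # row rebuilds ---------------------------------------------------------
    def _rebuild_local(self, l):
        st = self.state
        r = st.position(l)
        cmap = st.counts[l]
        res_entries, res_tot = [], 0.0
        for xk, nx in cmap.items():
            for yk, ny in cmap.items():
                if xk == yk:
                    continue
                rate = self._c(r, xk, yk) * nx * ny
                if rate > 0:
                    res_entries.append((rate, xk, yk))
                    res_tot += rate
        mut_entries, mut_tot = [], 0.0
        gamma = self.cfg.gamma
        if gamma > 0 and self.ker.theta_bar > 0:
            for xk, nx in cmap.items():
                rate = gamma * self._th(r, xk) * nx
                if rate > 0:
                    mut_entries.append((rate, xk))
                    mut_tot += rate
        self.res[l] = (res_entries, res_tot)
        self.mut[l] = (mut_entries, mut_tot)

    def _rebuild_mig(self, target, source):
        st = self.state
        gamma = self.cfg.gamma
        if gamma == 0 or self.ker.lam_bar == 0:
            self.mig[target][source] = ([], 0.0)
            return
        r, r2 = st.position(target), st.position(source)
        entries, tot = [], 0.0
        scale = gamma / st.K
        for xk, nx in st.counts[target].items():
            for yk, ny in st.counts[source].items():
                if xk == yk:
                    continue
                rate = scale * self._lam(r, xk, r2, yk) * nx * ny
                if rate > 0:
                    entries.append((rate, xk, yk))
                    tot += rate
        self.mig[target][source] = (entries, tot)

    def refresh_patch(self, l):
        self._rebuild_local(l)
        for l2 in range(self.state.K):
            if l2 != l:
                self._rebuild_mig(l, l2)
                self._rebuild_mig(l2, l)

    # channel totals -------------------------------------------------------
    def channel_totals(self):
        res = sum(t for _, t in self.res)
        mut = sum(t for _, t in self.mut)
        mig = sum(t for row in self.mig for cell in row if cell is not None for t in [cell[1]])
        return res, mut, mig


def total_event_rate(state: MicroState, config: MicroConfig):
    """Total state-changing event rate with per-channel breakdown.

    Returns ``(total, {"resampling": ..., "mutation": ..., "migration": ...})``.
    """
    table = _RateTable(state, config)
    res, mut, mig = table.channel_totals()
    return res + mut + mig, {"resampling": res, "mutation": mut, "migration": mig}


def _pick(entries, u):
    acc = 0.0
    for row in entries:
        acc += row[0]
        if u < acc:
            return row
    return entries[-1]


def simulate_micro(config: MicroConfig, state0: MicroState) -> JumpTrajectory:
    """Exact Gillespie realisation of the metapopulation process.

    Exponential waiting time at the current total (state-changing) rate;
    event channel and acting pair chosen proportionally to their rates.
    Mutations draw the new trait from ``Q_sampler``; migrations copy the
    source individual's trait over the target individual.
    """
    if state0.K != config.K:
        raise ValueError("state patch count does not match config")
    rng = np.random.default_rng(config.seed)
    state = state0.copy()
    table = _RateTable(state, config)
    traj = JumpTrajectory(t0=0.0, t_end=config.t_end, state0=state0.copy())
    t = 0.0
    needs_q = config.gamma > 0 and config.kernels.theta_bar > 0
    if needs_q and config.kernels.Q_sampler is None:
        raise ValueError("kernels.Q_sampler required when mutation is active")

    for _ in range(config.max_events):
        res_tot, mut_tot, mig_tot = table.channel_totals()
        total = res_tot + mut_tot + mig_tot
        if not np.isfinite(total):
            raise FloatingPointError("event rate overflow: unbounded kernel?")
        if total <= 0.0:
            break
        t += rng.exponential(1.0 / total)
        if t >= config.t_end:
            break
        u = rng.uniform(0.0, total)
        if u < res_tot:
            # within-patch resampling
            for l in range(state.K):
                entries, tot = table.res[l]
                if u < tot:
                    _, xk, yk = _pick(entries, u)
                    cmap = state.counts[l]
                    cmap[xk] -= 1
                    if cmap[xk] == 0:
                        del cmap[xk]
                    cmap[yk] = cmap.get(yk, 0) + 1
                    table.refresh_patch(l)
                    traj.times.append(t)
                    traj.events.append((t, "resample", l, xk, yk, -1))
                    break
                u -= tot
        elif u < res_tot + mut_tot:
            u -= res_tot
            for l in range(state.K):
                entries, tot = table.mut[l]
                if u < tot:
                    _, xk = _pick(entries, u)
                    y = as_trait(config.kernels.Q_sampler(rng, state.position(l), state.traits[xk]), config.kernels.d)
                    yk = trait_key(y)
                    state.traits.setdefault(yk, y)
                    cmap = state.counts[l]
                    cmap[xk] -= 1
                    if cmap[xk] == 0:
                        del cmap[xk]
                    cmap[yk] = cmap.get(yk, 0) + 1
                    table.refresh_patch(l)
                    traj.times.append(t)
                    traj.events.append((t, "mutate", l, xk, yk, -1))
                    break
                u -= tot
        else:
            u -= res_tot + mut_tot
            done = False
            for l in range(state.K):
                for l2 in range(state.K):
                    if l2 == l:
                        continue
                    entries, tot = table.mig[l][l2]
                    if u < tot:
                        _, xk, yk = _pick(entries, u)
                        cmap = state.counts[l]
                        cmap[xk] -= 1
                        if cmap[xk] == 0:
                            del cmap[xk]
                        cmap[yk] = cmap.get(yk, 0) + 1
                        table.refresh_patch(l)
                        traj.times.append(t)
                        traj.events.append((t, "migrate", l, xk, yk, l2))
                        done = True
                        break
                    u -= tot
                if done:
                    break
    else:
        raise RuntimeError("max_events exceeded before reaching t_end")

    traj.final_state = state
    # share the full trait registry (incl. mutation-created values) with the
    # stored initial state so the event list can be replayed from it
    traj.state0.traits = dict(state.traits)
    return traj


def empirical_measure(state: MicroState):
    """Empirical trait measure: atoms ``(l/K, x)`` with weight ``1/(NK)``."""
    from .meanfield import AtomicMeasure

    positions, traits, weights = [], [], []
    w = 1.0 / (state.N * state.K)
    for l in range(state.K):
        r = state.position(l)
        for xk, n in state.counts[l].items():
            positions.append(r)
            traits.append(state.traits[xk])
            weights.append(n * w)
    return AtomicMeasure(
        positions=np.array(positions),
        traits=np.array(traits),
        weights=np.array(weights),
    )


def dominant_trait(state: MicroState, patch: int):
    """The patch's common trait value if it is monomorphic, else ``None``."""
    if not 0 <= patch < state.K:
        raise IndexError(f"patch index {patch} out of range [0, {state.K})")
    cmap = state.counts[patch]
    if len(cmap) != 1:
        return None
    (xk,) = cmap
    return state.traits[xk]


def substitution_counts(traj: JumpTrajectory) -> np.ndarray:
    """Per-patch counts of dominant-trait changes along a trajectory.

    Replays the event list from the initial state; each time a patch returns
    to monomorphism at a trait different from its previous dominant value,
    one substitution is counted.  All patches of the initial state must be
    monomorphic.
    """
    state = traj.state0.copy()
    dominant = []
    for l in range(state.K):
        x = dominant_trait(state, l)
        if x is None:
            raise ValueError("substitution counting requires a monomorphic initial state")
        dominant.append(trait_key(x))
    counts = np.zeros(state.K, dtype=int)
    for (_, _, l, xk, yk, _) in traj.events:
        cmap = state.counts[l]
        cmap[xk] -= 1
        if cmap[xk] == 0:
            del cmap[xk]
        cmap[yk] = cmap.get(yk, 0) + 1
        if len(cmap) == 1:
            (new_dom,) = cmap
            if new_dom != dominant[l]:
                counts[l] += 1
                dominant[l] = new_dom
    return counts
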