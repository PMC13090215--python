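"""Model-defining rate kernels and the two-type Moran fixation probability.

A model instance is a :class:`ModelKernels`: the within-deme resampling rate
``c(r, x, y)`` (the rate at which one individual with trait ``x`` is replaced
by a copy of an individual with trait ``y`` in the deme at position ``r``),
the per-capita mutation rate ``theta(r, x)`` with mutation law ``Q``, and the
pairwise migration kernel ``lam((r, x), (r', y))``.  Selection acts only
through ``c``: an invader ``y`` in a resident-``x`` deme of size ``N`` fixes
with the classical two-type Moran probability

    alpha(r, y, x) = 1 / sum_{k=0}^{N-1} rho^k,   rho = c(r, y, x) / c(r, x, y),

which reduces to the neutral value ``1/N`` when forward and backward rates
coincide.  The invader-slot gradient of the relative fitness
``Fit(r, y, x) = log(c(r, x, y) / c(r, y, x))`` drives the advection term of
the canonical jump-diffusion and satisfies the identity

    grad_y alpha(r, x, x) = (N - 1) / (2 N) * grad_y Fit(r, x, x),

used as a cross-check throughout the test suite.

Both the heterogeneous and homogeneous forms of the limit equations take
gradients of ``Fit`` in the slot holding the *invading* trait; this module
exposes a single :func:`selection_gradient` for that purpose so that the two
notational conventions cannot diverge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "ModelKernels",
    "fixation_probability",
    "fixation_oracle",
    "relative_fitness",
    "selection_gradient",
    "fixation_gradient",
    "mutation_covariance",
    "preset_kernels",
    "PRESET_NAMES",
    "as_trait",
    "trait_key",
]


def as_trait(x, d: int | None = None) -> np.ndarray:
    """Coerce a scalar/sequence to a 1-d float trait vector."""
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"trait must be a scalar or 1-d vector, got shape {arr.shape}")
    if d is not None and arr.shape[0] != d:
        raise ValueError(f"trait has dimension {arr.shape[0]}, expected {d}")
    return arr


def trait_key(x) -> tuple:
    """Hashable key for a trait value (exact bit equality)."""
    return tuple(np.atleast_1d(np.asarray(x, dtype=float)).tolist())


@dataclass
class ModelKernels:
    """Rate functions defining one metapopulation model instance.

    Parameters
    ----------
    N : int
        Deme size (individuals per patch), ``N >= 1``.
    d : int
        Trait dimension.
    c : callable ``(r, x, y) -> float``
        Within-deme resampling rate: an ``x`` individual is replaced by a copy
        of a ``y`` individual at this rate (per ordered pair).  Must be
        non-negative, bounded and measurable; strictly positive wherever a
        fixation probability or fitness is required.
    theta : callable ``(r, x) -> float``
        Per-capita mutation rate, non-negative.
    lam : callable ``(r, x, r2, y) -> float``
        Migration kernel: rate factor at which the resident ``x`` at position
        ``r`` is replaced by a migrant copy of ``y`` from position ``r2``.
    Q_sampler : callable ``(rng, r, x) -> y``, optional
        Draws a mutant trait from the mutation law ``Q(r, x, dy)``.
    Q_support : callable ``(r, x) -> list[(y, prob)]``, optional
        Finite support of ``Q`` when the mutation law is discrete; enables
        exact rate sums in the substitution-sequence and atomic-measure
        solvers.
    m_sampler : callable ``(rng, r, x) -> h``, optional
        Draws a centred scaled mutation step ``h`` (the mutant trait is
        ``x + eps * h``).
    Sigma_exact : callable ``(r, x) -> (d, d) array``, optional
        Closed-form covariance of the scaled steps, when known.
    c_bar, theta_bar, lam_bar : float
        Finite upper bounds on the kernels over the state region of interest;
        they drive thinning proposal rates and are checked opportunistically
        (a kernel evaluation exceeding its bound raises).
    homogeneous : bool
        True when none of the rates depend on position (mean-field dispersal);
        required by the McKean-Vlasov and replicator reductions.
    """

    N: int
    d: int
    c: Callable[[float, np.ndarray, np.ndarray], float]
    theta: Callable[[float, np.ndarray], float]
    lam: Callable[[float, np.ndarray, float, np.ndarray], float]
    Q_sampler: Optional[Callable] = None
    Q_support: Optional[Callable] = None
    m_sampler: Optional[Callable] = None
    Sigma_exact: Optional[Callable] = None
    c_bar: float = 1.0
    theta_bar: float = 0.0
    lam_bar: float = 0.0
    homogeneous: bool = True
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("deme size N must be >= 1")
        if self.d < 1:
            raise ValueError("trait dimension d must be >= 1")
        for bound, label in ((self.c_bar, "c_bar"), (self.theta_bar, "theta_bar"), (self.lam_bar, "lam_bar")):
            if not np.isfinite(bound) or bound < 0:
                raise ValueError(f"bound {label} must be finite and non-negative")

    # -- bound-checked evaluations (opportunistic Assumption-1 guard) -------
    def eval_c(self, r: float, x, y) -> float:
        val = float(self.c(r, x, y))
        if val < 0 or val > self.c_bar * (1 + 1e-12):
            raise ValueError(f"c({r},{x},{y}) = {val} violates [0, c_bar={self.c_bar}]")
        return val

    def eval_theta(self, r: float, x) -> float:
        val = float(self.theta(r, x))
        if val < 0 or val > self.theta_bar * (1 + 1e-12):
            raise ValueError(f"theta({r},{x}) = {val} violates [0, theta_bar={self.theta_bar}]")
        return val

    def eval_lam(self, r: float, x, r2: float, y) -> float:
        val = float(self.lam(r, x, r2, y))
        if val < 0 or val > self.lam_bar * (1 + 1e-12):
            raise ValueError(f"lam(({r},{x}),({r2},{y})) = {val} violates [0, lam_bar={self.lam_bar}]")
        return val

    def invasion_probability(self, r: float, y, x) -> float:
        """Fixation probability alpha(r, y, x) of a single ``y`` invader."""
        return fixation_probability(self.eval_c(r, x, y), self.eval_c(r, y, x), self.N)


def fixation_probability(c_forward: float, c_backward: float, N: int) -> float:
    """Closed-form fixation probability of a single invader in a Moran deme.

    ``c_forward = c(r, x, y)`` is the rate at which the resident ``x`` is
    replaced by the invader ``y`` (forward, favouring invasion);
    ``c_backward = c(r, y, x)`` the reverse.  Returns

        alpha = (sum_{k=0}^{N-1} rho^k)^{-1},   rho = c_backward / c_forward,

    computed through the geometric closed form ``(1 - rho) / (1 - rho^N)``
    with a log-space branch when ``rho^N`` overflows, and ``alpha = 0`` when
    ``c_forward = 0`` (the invader can never displace a resident).
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if c_forward < 0 or c_backward < 0:
        raise ValueError("resampling rates must be non-negative")
    if c_forward == 0.0:
        return 0.0
    if N == 1:
        return 1.0
    rho = c_backward / c_forward
    if rho == 0.0:
        return 1.0
    log_rho = math.log(rho)
    if abs(rho - 1.0) < 1e-12:
        # rho ~ 1: geometric sum ~ N (1 + (N-1)/2 (rho-1)); direct sum is exact
        # and cheap for the N of interest.
        return 1.0 / sum(rho**k for k in range(N))
    if N * log_rho > 690.0:  # rho^N overflows: alpha ~ (rho - 1) rho^{-N}
        return math.exp(math.log(rho - 1.0) - N * log_rho)
    return (1.0 - rho) / (1.0 - rho**N)


def fixation_oracle(c_forward: float, c_backward: float, N: int) -> float:
    """Brute-force fixation probability via the birth-death first-step system.

    The resident count ``n`` performs a birth-death chain on ``{0, ..., N}``
    with up-rate ``c_backward * n (N - n)`` and down-rate
    ``c_forward * n (N - n)``, started at ``n = N - 1``; the invader fixes
    when the chain is absorbed at 0.  Solved as a linear system, independent
    of the geometric closed form.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if c_forward < 0 or c_backward < 0:
        raise ValueError("resampling rates must be non-negative")
    if N == 1:
        return 1.0 if c_forward > 0 else 0.0
    if c_forward == 0.0:
        return 0.0
    # h(n) = P(hit 0 | resident count n), h(0) = 1, h(N) = 0;
    # (up + down) h(n) = up h(n+1) + down h(n-1) on 1 <= n <= N-1.
    m = N - 1
    A = np.zeros((m, m))
    b = np.zeros(m)
    for i, n in enumerate(range(1, N)):
        up = c_backward * n * (N - n)
        down = c_forward * n * (N - n)
        A[i, i] = up + down
        if i + 1 < m:
            A[i, i + 1] = -up
        if i - 1 >= 0:
            A[i, i - 1] = -down
        else:
            b[i] = down  # h(0) = 1 contributes down * 1
    h = np.linalg.solve(A, b)
    return float(h[-1])  # start at n = N - 1


def relative_fitness(kernels: ModelKernels, r: float, y, x) -> float:
    """Relative fitness ``Fit(r, y, x) = log(c(r, x, y) / c(r, y, x))``.

    Antisymmetric in ``(y, x)``; positive when the invader ``y`` displaces
    residents faster than it is displaced.  Raises when either rate is not
    strictly positive (the log-ratio is undefined).
    """
    cf = kernels.eval_c(r, x, y)
    cb = kernels.eval_c(r, y, x)
    if cf <= 0 or cb <= 0:
        raise ValueError("relative fitness requires strictly positive resampling rates")
    # log(cf) - log(cb) rather than log(cf/cb): antisymmetry in (y, x) is
    # then exact in floating point
    return math.log(cf) - math.log(cb)


def selection_gradient(kernels: ModelKernels, r: float, x, h_fd: float = 1e-5) -> np.ndarray:
    """Invader-slot fitness gradient ``grad_y Fit(r, y, x) |_{y=x}``.

    Central finite differences with step ``h_fd`` (default 1e-5, balancing
    truncation and round-off for O(1) kernels); truncation error is
    ``O(h_fd**2)``.
    """
    x = as_trait(x, kernels.d)
    if h_fd <= 0:
        raise ValueError("h_fd must be positive")
    grad = np.empty(kernels.d)
    for i in range(kernels.d):
        e = np.zeros(kernels.d)
        e[i] = h_fd
        fp = relative_fitness(kernels, r, x + e, x)
        fm = relative_fitness(kernels, r, x - e, x)
        if not (np.isfinite(fp) and np.isfinite(fm)):
            raise FloatingPointError("non-finite kernel values near the expansion point")
        grad[i] = (fp - fm) / (2.0 * h_fd)
    return grad


def fixation_gradient(kernels: ModelKernels, r: float, x, h_fd: float = 1e-5) -> np.ndarray:
    """Invader-slot gradient of the fixation probability, ``grad_y alpha(r, x, x)``.

    Finite-difference companion to :func:`selection_gradient`; the two are
    linked by ``grad_y alpha = (N - 1)/(2 N) grad_y Fit`` at ``y = x``.
    """
    x = as_trait(x, kernels.d)
    grad = np.empty(kernels.d)
    for i in range(kernels.d):
        e = np.zeros(kernels.d)
        e[i] = h_fd
        ap = kernels.invasion_probability(r, x + e, x)
        am = kernels.invasion_probability(r, x - e, x)
        grad[i] = (ap - am) / (2.0 * h_fd)
    return grad


def mutation_covariance(
    kernels: ModelKernels,
    r: float,
    x,
    n_mc: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Covariance ``Sigma(r, x) = E[h h^T]`` of the scaled mutation steps.

    Uses the preset closed form when available, otherwise a Monte-Carlo
    estimate from ``m_sampler`` (``n_mc`` draws).  Returns ``(Sigma, sigma)``
    with ``sigma`` the symmetric PSD square root, ``sigma sigma^T = Sigma``.
    """
    x = as_trait(x, kernels.d)
    if kernels.Sigma_exact is not None:
        Sigma = np.atleast_2d(np.asarray(kernels.Sigma_exact(r, x), dtype=float))
    else:
        if kernels.m_sampler is None:
            raise ValueError("no step sampler or exact covariance available")
        if n_mc < 2:
            raise ValueError("n_mc must be >= 2")
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        draws = np.array([as_trait(kernels.m_sampler(gen, r, x), kernels.d) for _ in range(n_mc)])
        if not np.all(np.isfinite(draws)):
            raise FloatingPointError("non-finite mutation steps")
        Sigma = draws.T @ draws / n_mc
    Sigma = 0.5 * (Sigma + Sigma.T)
    vals, vecs = np.linalg.eigh(Sigma)
    vals = np.clip(vals, 0.0, None)
    sigma = (vecs * np.sqrt(vals)) @ vecs.T
    return Sigma, sigma


# ---------------------------------------------------------------------------
# Preset kernel registry
# ---------------------------------------------------------------------------

def _gaussian_step(rng, r, x):
    return rng.standard_normal(x.shape[0] if hasattr(x, "shape") else 1)


def _make_neutral(N, d, c0=1.0, theta0=1.0, lam0=1.0, mut_scale=1.0):
    """Neutral resampling: alpha = 1/N everywhere; Gaussian mutation steps."""
    return ModelKernels(
        N=N, d=d,
        c=lambda r, x, y: c0,
        theta=lambda r, x: theta0,
        lam=lambda r, x, r2, y: lam0,
        Q_sampler=lambda rng, r, x: as_trait(x, d) + mut_scale * rng.standard_normal(d),
        m_sampler=lambda rng, r, x: rng.standard_normal(d),
        Sigma_exact=lambda r, x: np.eye(d),
        c_bar=c0, theta_bar=theta0, lam_bar=lam0,
        homogeneous=True, name="neutral",
        params=dict(c0=c0, theta0=theta0, lam0=lam0, mut_scale=mut_scale),
    )


def _make_directional_1d(N, d, s=0.5, theta0=1.0, lam0=0.0, box=(0.0, 1.0), mut_scale=1.0):
    """Directional selection in 1-d: c(r, x, y) = exp(s (y - x)).

    Larger traits invade faster; Fit(r, y, x) = 2 s (y - x).  Bounds hold on
    the trait interval ``box``.
    """
    if d != 1:
        raise ValueError("directional_1d is one-dimensional")
    lo, hi = box
    return ModelKernels(
        N=N, d=1,
        c=lambda r, x, y: math.exp(s * (float(np.atleast_1d(y)[0]) - float(np.atleast_1d(x)[0]))),
        theta=lambda r, x: theta0,
        lam=lambda r, x, r2, y: lam0,
        Q_sampler=lambda rng, r, x: as_trait(x, 1) + mut_scale * rng.standard_normal(1),
        m_sampler=lambda rng, r, x: rng.standard_normal(1),
        Sigma_exact=lambda r, x: np.eye(1),
        c_bar=math.exp(abs(s) * (hi - lo)), theta_bar=theta0, lam_bar=lam0,
        homogeneous=True, name="directional_1d",
        params=dict(s=s, theta0=theta0, lam0=lam0, box=box, mut_scale=mut_scale),
    )


def _make_gaussian_stabilizing(N, d, s=1.0, x0=0.0, theta0=1.0, lam0=0.0, box=(-2.0, 2.0), mut_scale=1.0):
    """Stabilizing selection: c(r, x, y) = exp(s/2 (|x - x0|^2 - |y - y0|^2)).

    Fit(r, y, x) = s (|x - x0|^2 - |y - x0|^2) is maximised at y = x0; the
    selection gradient at x is -2 s (x - x0), pulling traits toward the
    optimum.
    """
    x0v = np.full(d, float(x0)) if np.isscalar(x0) else as_trait(x0, d)
    lo, hi = box
    half_span = max(abs(lo - np.min(x0v)), abs(hi - np.max(x0v)))
    return ModelKernels(
        N=N, d=d,
        c=lambda r, x, y: math.exp(
            0.5 * s * (float(np.sum((as_trait(x, d) - x0v) ** 2)) - float(np.sum((as_trait(y, d) - x0v) ** 2)))
        ),
        theta=lambda r, x: theta0,
        lam=lambda r, x, r2, y: lam0,
        Q_sampler=lambda rng, r, x: as_trait(x, d) + mut_scale * rng.standard_normal(d),
        m_sampler=lambda rng, r, x: rng.standard_normal(d),
        Sigma_exact=lambda r, x: np.eye(d),
        c_bar=math.exp(0.5 * abs(s) * d * half_span**2), theta_bar=theta0, lam_bar=lam0,
        homogeneous=True, name="gaussian_stabilizing",
        params=dict(s=s, x0=x0, theta0=theta0, lam0=lam0, box=box, mut_scale=mut_scale),
    )


def _make_case1_exclusion(N, d):
    """Competitive-exclusion migration kernel on traits in [0, 1].

    Neutral resampling (alpha = 1/N) with lam(x, y) = x (1 + y) / N, so the
    migration-fixation rate is lam * alpha = x (1 + y) / N^2 and the replicator
    interaction is G(y, x) = x - y: the smallest trait value excludes all
    others.
    """
    if d != 1:
        raise ValueError("case1_exclusion is one-dimensional")
    return ModelKernels(
        N=N, d=1,
        c=lambda r, x, y: 1.0,
        theta=lambda r, x: 0.0,
        lam=lambda r, x, r2, y: float(np.atleast_1d(x)[0]) * (1.0 + float(np.atleast_1d(y)[0])) / N,
        c_bar=1.0, theta_bar=0.0, lam_bar=2.0 / N,
        homogeneous=True, name="case1_exclusion", params=dict(),
    )


def _make_case2_cycling(N, d):
    """Cycling migration kernel on traits in [0, 1].

    Neutral resampling with lam(x, y) = (1 + sin(2 pi (x - y))) / N, giving
    migration-fixation rate (1 + sin(2 pi (x - y))) / N^2 and replicator
    interaction G(y, x) = 2 sin(2 pi (x - y)); no trait dominates and the
    replicator orbits cycle around an interior equilibrium.
    """
    if d != 1:
        raise ValueError("case2_cycling is one-dimensional")
    return ModelKernels(
        N=N, d=1,
        c=lambda r, x, y: 1.0,
        theta=lambda r, x: 0.0,
        lam=lambda r, x, r2, y: (1.0 + math.sin(2.0 * math.pi * (float(np.atleast_1d(x)[0]) - float(np.atleast_1d(y)[0])))) / N,
        c_bar=1.0, theta_bar=0.0, lam_bar=2.0 / N,
        homogeneous=True, name="case2_cycling", params=dict(),
    )


_PRESETS = {
    "neutral": _make_neutral,
    "directional_1d": _make_directional_1d,
    "gaussian_stabilizing": _make_gaussian_stabilizing,
    "case1_exclusion": _make_case1_exclusion,
    "case2_cycling": _make_case2_cycling,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def preset_kernels(name: str, N: int = 5, d: int = 1, **params) -> ModelKernels:
    """Build a named preset :class:`ModelKernels`.

    Presets carry exact analytic bounds and covariances, making downstream
    thinning exact and tests reproducible.  Available: ``neutral``,
    ``directional_1d``, ``gaussian_stabilizing``, ``case1_exclusion``,
    ``case2_cycling``.
    """
    try:
        factory = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}") from None
    return factory(N, d, **params)


def two_trait_kernels(
    N: int = 5,
    a: float = 0.0,
    b: float = 1.0,
    c_ab: float = 2.0,
    c_ba: float = 1.0,
    theta0: float = 1.0,
    lam0: float = 0.0,
) -> ModelKernels:
    """Discrete two-trait kernel: mutation flips between traits ``a`` and ``b``.

    ``c_ab`` is the rate at which an ``a`` individual is replaced by a ``b``
    copy (so ``c_ab > c_ba`` favours ``b``); all other resampling is neutral
    at rate 1.  Used for exact-rate substitution tests.
    """
    av, bv = float(a), float(b)

    def c(r, x, y):
        xv, yv = float(np.atleast_1d(x)[0]), float(np.atleast_1d(y)[0])
        if xv == av and yv == bv:
            return c_ab
        if xv == bv and yv == av:
            return c_ba
        return 1.0

    def q_sampler(rng, r, x):
        xv = float(np.atleast_1d(x)[0])
        return np.array([bv if xv == av else av])

    def q_support(r, x):
        xv = float(np.atleast_1d(x)[0])
        return [(np.array([bv if xv == av else av]), 1.0)]

    return ModelKernels(
        N=N, d=1, c=c,
        theta=lambda r, x: theta0,
        lam=lambda r, x, r2, y: lam0,
        Q_sampler=q_sampler, Q_support=q_support,
        c_bar=max(c_ab, c_ba, 1.0), theta_bar=theta0, lam_bar=lam0,
        homogeneous=True, name="two_trait",
        params=dict(a=a, b=b, c_ab=c_ab, c_ba=c_ba, theta0=theta0, lam0=lam0),
    )
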