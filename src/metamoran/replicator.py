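"""Small-mutation, natural-timescale limit: migration-fixation weight
dynamics and the antisymmetric Lotka-Volterra replicator reduction.

When mutation steps vanish and time is not accelerated, diversity can only
redistribute among the ``n`` trait values initially present.  The spatial
weight field ``w_i(r)`` (the local frequency of trait ``x^i`` at position
``r``) obeys an integro-differential migration-fixation system; under
mean-field dispersal its spatial means ``wbar_i`` close into the
conservative replicator equation

    d wbar_i / dt = wbar_i sum_j a_ij wbar_j,

with the antisymmetric interaction matrix
``a_ij = G(x^i, x^j)``, ``G(y, x) = N^2 (lam(x, y) alpha(y, x) -
lam(y, x) alpha(x, y))`` — a zero-sum game between trait values.  A trait
whose interaction row is strictly positive competitively excludes all
others; when instead a strictly positive equilibrium ``w*`` exists
(``A w* = 0``), the quantity ``sum_i w*_i log wbar_i`` is conserved and
orbits cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space
from scipy.optimize import linprog

from .kernels import ModelKernels, as_trait

__all__ = [
    "InteractionMatrix",
    "build_interaction_matrix",
    "solve_replicator",
    "solve_spatial_weights",
    "exclusion_winner",
    "interior_equilibrium",
]

_HOM_R = 0.5  # position argument used under homogeneity; value immaterial


@dataclass
class InteractionMatrix:
    """Antisymmetric replicator interaction matrix a_ij = G(x^i, x^j)."""

    traits: np.ndarray  # (n, d)
    A: np.ndarray       # (n, n), A + A^T = 0 exactly

    @property
    def n(self) -> int:
        return self.A.shape[0]


def build_interaction_matrix(traits, kernels: ModelKernels) -> InteractionMatrix:
    """Interaction matrix of the mean-weight replicator system.

    ``a_ij = G(x^i, x^j)`` with ``G(y, x) = N^2 (lam(x, y) alpha(y, x) -
    lam(y, x) alpha(x, y))``; the upper triangle is computed and negated
    into the lower one, so antisymmetry is exact by construction.  Requires
    homogeneous kernels with pairwise positive resampling rates.
    """
    if not kernels.homogeneous:
        raise ValueError(
            "interaction matrices require homogeneous kernels; "
            "use solve_spatial_weights for heterogeneous models"
        )
    xs = np.array([as_trait(x, kernels.d) for x in traits])
    n = xs.shape[0]
    N = kernels.N
    A = np.zeros((n, n))
    r = _HOM_R
    for i in range(n):
        for j in range(i + 1, n):
            xi, xj = xs[i], xs[j]
            # G(x^i, x^j): invader x^i against resident x^j
            gain = kernels.eval_lam(r, xj, r, xi) * kernels.invasion_probability(r, xi, xj)
            loss = kernels.eval_lam(r, xi, r, xj) * kernels.invasion_probability(r, xj, xi)
            A[i, j] = N**2 * (gain - loss)
            A[j, i] = -A[i, j]
    return InteractionMatrix(traits=xs, A=A)


def solve_replicator(
    A: InteractionMatrix | np.ndarray,
    w0,
    t_end: float,
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-10,
    atol: float = 1e-14,
):
    """Integrate the replicator ODE ``dw_i/dt = w_i (A w)_i`` from ``w0``.

    ``w0`` must lie on the simplex to within 1e-12.  Antisymmetric systems
    are non-stiff but conservation-sensitive, so a tight-tolerance adaptive
    explicit Runge-Kutta scheme is used; the trajectory stays on the simplex
    up to solver tolerance (conservation is asserted by tests, never
    enforced by renormalisation).  Returns ``(times, W)`` with ``W`` of
    shape ``(T, n)``.
    """
    mat = A.A if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if np.any(w0 < -1e-12) or abs(w0.sum() - 1.0) > 1e-12:
        raise ValueError("w0 must lie on the probability simplex (tolerance 1e-12)")

    def rhs(t, w):
        return w * (mat @ w)

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (0.0, t_end), w0, t_eval=t_eval, rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise RuntimeError(f"replicator integration failed: {sol.message}")
    return sol.t, sol.y.T


def solve_spatial_weights(
    traits,
    w0_grid,
    kernels: ModelKernels,
    t_end: float,
    t_eval: Optional[Sequence[float]] = None,
    rtol: float = 1e-10,
    atol: float = 1e-14,
):
    """Integrate the spatial migration-fixation weight system on a grid.

    ``w0_grid`` has shape ``(n, m)``: the weight of trait ``x^i`` at each of
    ``m`` uniform midpoint grid positions ``r_k = (k + 1/2)/m``; each column
    must sum to 1 (the local weights form a probability vector).  Position
    integrals are midpoint-rule means over the grid, which is
    positivity-preserving and matches the equal-patch-size convention; with
    ``m = 1`` the equations collapse exactly onto the mean-weight replicator
    ODE.  Returns ``(times, W)`` with ``W`` of shape ``(T, n, m)``.
    """
    xs = np.array([as_trait(x, kernels.d) for x in traits])
    W0 = np.atleast_2d(np.asarray(w0_grid, dtype=float))
    n, m = W0.shape
    if xs.shape[0] != n:
        raise ValueError("w0_grid rows must match the number of traits")
    if np.any(np.abs(W0.sum(axis=0) - 1.0) > 1e-10):
        raise ValueError("local weights must sum to 1 at every grid point")
    rs = (np.arange(m) + 0.5) / m
    N = kernels.N

    alpha = np.empty((m, n, n))  # alpha[k, i, j]: invader x_j vs resident x_i at r_k
    for k, r in enumerate(rs):
        for i in range(n):
            for j in range(n):
                alpha[k, i, j] = kernels.invasion_probability(r, xs[j], xs[i]) if i != j else 0.0
    lam4 = np.empty((m, n, m, n))
    for k, r in enumerate(rs):
        for i in range(n):
            for l, r2 in enumerate(rs):
                for j in range(n):
                    lam4[k, i, l, j] = kernels.eval_lam(r, xs[i], r2, xs[j]) if i != j else 0.0

    def rhs(t, w_flat):
        W = w_flat.reshape(n, m).T  # (m, n): grid-major
        Lam = np.einsum("kilj,lj->kij", lam4, W) / m  # integral -> grid mean
        out = N**2 * W * np.einsum("kij,kij->ki", alpha, Lam)
        inc = N**2 * np.einsum("kj,kji,kji->ki", W, alpha, Lam)
        return (inc - out).T.reshape(-1)

    if t_eval is None:
        t_eval = np.linspace(0.0, t_end, 201)
    t_eval = np.asarray(t_eval, dtype=float)
    sol = solve_ivp(rhs, (0.0, t_end), W0.reshape(-1), t_eval=t_eval, rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise RuntimeError(f"spatial weight integration failed: {sol.message}")
    return sol.t, sol.y.T.reshape(len(sol.t), n, m)


def exclusion_winner(A: InteractionMatrix | np.ndarray, w0) -> Optional[int]:
    """Index of the competitively excluding trait, if any.

    Returns ``i*`` when ``w0[i*] > 0`` and ``a_{i* j} > 0`` for every
    ``j != i*`` (a strictly positive interaction row guarantees
    ``wbar_{i*} -> 1``); ``None`` otherwise.
    """
    mat = A.A if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    n = mat.shape[0]
    for i in range(n):
        if w0[i] <= 0:
            continue
        row = np.delete(mat[i], i)
        if np.all(row > 0):
            return i
    return None


def interior_equilibrium(A: InteractionMatrix | np.ndarray, tol: float = 1e-10) -> Optional[np.ndarray]:
    """Strictly positive normalised null vector of ``A``, if one exists.

    Searches the nullspace for a probability vector ``w*`` with
    ``A w* = 0`` and all components strictly positive (the interior
    equilibrium around which zero-sum replicator orbits cycle).  Returns
    ``None`` when no such vector exists, e.g. under a strictly dominant row.
    """
    mat = A.A if isinstance(A, InteractionMatrix) else np.asarray(A, dtype=float)
    n = mat.shape[0]
    ns = null_space(mat, rcond=1e-12)
    if ns.shape[1] == 0:
        return None
    if ns.shape[1] == 1:
        v = ns[:, 0]
        if np.all(v > 0) or np.all(v < 0):
            w = np.abs(v)
            w = w / w.sum()
            if np.linalg.norm(mat @ w) <= tol:
                return w
        return None
    # multi-dimensional nullspace: look for a strictly positive combination
    eps = 1e-9
    res = linprog(
        c=np.zeros(n),
        A_eq=np.vstack([mat, np.ones((1, n))]),
        b_eq=np.append(np.zeros(n), 1.0),
        bounds=[(eps, None)] * n,
        method="highs",
    )
    if res.status == 0 and np.all(res.x > 0):
        w = res.x / res.x.sum()
        if np.linalg.norm(mat @ w) <= tol:
            return w
    return None
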