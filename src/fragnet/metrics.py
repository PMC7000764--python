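"""Fragility and responsiveness metrics for linear dynamic networks.

Fragility is measured through the (complex, unstructured) stability radius

    r(A) = min { ||Delta|| : A + Delta is unstable },

the spectral norm of the smallest perturbation that pushes an eigenvalue
across the stability boundary.  For a stable continuous-time matrix it
equals ``min_w sigma_min(A - i w I)`` over real frequencies w; in discrete
time the imaginary axis is replaced by the unit circle.  Responsiveness is
the average singular value of the controllability Gramian,
``sigma_bar(G) = trace(G)/n`` for the PSD Gramian.  Both are linked by a
family of tradeoff inequalities evaluated in :func:`evaluate_bounds`.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg as sla
from scipy.optimize import minimize_scalar

from .network import LinearNetwork, TimeMode
from .reports import BoundReport, FragilityReport, GramianReport

__all__ = [
    "StabilityError",
    "ControllabilityError",
    "spectral_stability_margin",
    "stability_radius",
    "stability_radius_grid",
    "eigvec_condition",
    "non_normality",
    "average_singular_value",
    "controllability_gramian",
    "min_control_energy",
    "fragility_report",
    "evaluate_bounds",
    "is_normal",
    "is_symmetric",
]

#: eigenvector-matrix condition estimate above which a matrix is declared
#: numerically defective and kappa(V) undefined
_DEFECTIVE_CUTOFF = 1.0 / np.finfo(float).eps


class StabilityError(ValueError):
    """Raised when an operation requires a stable network but got an unstable one."""


class ControllabilityError(ValueError):
    """Raised when the Gramian is singular: the network is not controllable."""


def _check_square(A: np.ndarray) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    return A


def spectral_stability_margin(A, time_mode: TimeMode = TimeMode.CONTINUOUS) -> float:
    """Distance of the spectrum of A from the stability boundary.

    Continuous time: ``s(A) = -max_i Re(lambda_i)``, the distance of the
    eigenvalues from the imaginary axis.  Discrete time:
    ``1 - max_i |lambda_i|``, the distance from the unit circle.  A
    negative value signals instability.
    """
    A = _check_square(A)
    lam = np.linalg.eigvals(A)
    if TimeMode(time_mode) is TimeMode.CONTINUOUS:
        return float(-np.max(lam.real))
    return float(1.0 - np.max(np.abs(lam)))


def non_normality(A) -> float:
    """Spectral norm of ``A - A^T``: the asymmetry (non-normality) degree.

    Zero exactly for symmetric matrices; governs transient amplification.
    """
    A = _check_square(A)
    return float(np.linalg.norm(A - A.T, 2))


def is_symmetric(A, rtol: float = 1e-8) -> bool:
    A = _check_square(A)
    scale = max(1.0, float(np.linalg.norm(A, "fro")))
    return float(np.linalg.norm(A - A.T, "fro")) <= rtol * scale


def is_normal(A, rtol: float = 1e-8) -> bool:
    """Whether ``A A^T = A^T A`` within a relative Frobenius tolerance."""
    A = _check_square(A)
    scale = max(1.0, float(np.linalg.norm(A, "fro")) ** 2)
    comm = A @ A.T - A.T @ A
    return float(np.linalg.norm(comm, "fro")) <= rtol * scale


def eigvec_condition(A) -> float:
    """2-norm condition number kappa(V) of the eigenvector matrix of A.

    The eigenvector columns are scaled to unit Euclidean norm (the bounds
    below hold for any diagonalizing V, and unit columns are the canonical
    choice).  Returns ``nan`` when V is numerically singular, i.e. the
    matrix is defective to machine precision.
    """
    A = _check_square(A)
    _, V = np.linalg.eig(A)
    V = V / np.linalg.norm(V, axis=0, keepdims=True)
    sv = np.linalg.svd(V, compute_uv=False)
    if sv[-1] <= 0 or sv[0] / sv[-1] > _DEFECTIVE_CUTOFF:
        return math.nan
    return float(sv[0] / sv[-1])


def average_singular_value(M) -> float:
    """Mean of all singular values of M; ``trace(M)/n`` when M is PSD."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix has no singular values")
    sv = np.linalg.svd(M, compute_uv=False)
    return float(np.mean(sv))


# ---------------------------------------------------------------------------
# stability radius
# ---------------------------------------------------------------------------


def _has_imaginary_eig(A: np.ndarray, eps: float, tau: float) -> bool:
    """Hamiltonian test: H(eps) has a purely imaginary eigenvalue iff
    ``eps >= min_w sigma_min(A - i w I)``."""
    n = A.shape[0]
    I = np.eye(n)
    H = np.block([[A, -eps * I], [eps * I, -A.T]])
    lam = np.linalg.eigvals(H)
    return bool(np.min(np.abs(lam.real)) <= tau)


def _has_unit_circle_eig(A: np.ndarray, eps: float, tau: float) -> bool:
    """Symplectic-pencil test: the pencil (M, N) below has a generalized
    eigenvalue on the unit circle iff ``eps >= min_t sigma_min(A - e^{it} I)``."""
    n = A.shape[0]
    I = np.eye(n)
    Z = np.zeros((n, n))
    M = np.block([[A, -eps * I], [Z, I]])
    N = np.block([[I, Z], [-eps * I, A.T]])
    lam = sla.eigvals(M, N)
    lam = lam[np.isfinite(lam)]
    if lam.size == 0:
        return False
    return bool(np.min(np.abs(np.abs(lam) - 1.0)) <= tau)


def stability_radius(A, time_mode: TimeMode = TimeMode.CONTINUOUS,
                     tol: float = 1e-6) -> float:
    """Complex unstructured stability radius of A, to absolute accuracy ``tol``.

    Computed by bisection on the perturbation size ``eps``: ``eps`` exceeds
    the radius exactly when the Hamiltonian matrix
    ``[[A, -eps I], [eps I, -A^T]]`` has a purely imaginary eigenvalue
    (continuous time) or when the analogous symplectic pencil has a
    generalized eigenvalue on the unit circle (discrete time).  The initial
    bracket is ``[0, s(A)]``, valid because ``r(A) <= s(A)``.

    Returns 0 for an unstable matrix: the empty perturbation already
    destabilizes it.
    """
    A = _check_square(A)
    if not np.all(np.isfinite(A)):
        raise ValueError("matrix contains NaN or Inf entries")
    if tol <= 0:
        raise ValueError(f"tol must be positive, got {tol}")
    mode = TimeMode(time_mode)
    s = spectral_stability_margin(A, mode)
    if s <= 0:
        return 0.0

    tau = 1e-7 * max(1.0, float(np.linalg.norm(A, 2)))
    test = _has_imaginary_eig if mode is TimeMode.CONTINUOUS else _has_unit_circle_eig
    lo, hi = 0.0, s
    # the margin itself always passes the test (r <= s); guard anyway
    if not test(A, hi, tau):
        hi = s * (1.0 + 1e-9) + tol
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if test(A, mid, tau):
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi)


def stability_radius_grid(A, time_mode: TimeMode = TimeMode.CONTINUOUS,
                          n_grid: int = 2001) -> float:
    """Independent dense-grid evaluation of the stability radius.

    Scans ``sigma_min(A - i w I)`` over ``|w| <= 3 ||A||`` (continuous) or
    ``sigma_min(A - e^{it} I)`` over ``t in [0, 2 pi)`` (discrete) on a
    regular grid, then refines the best bracket with a bounded scalar
    minimizer.  Slower than the bisection but entirely independent of it;
    used as the cross-check oracle.
    """
    A = _check_square(A)
    mode = TimeMode(time_mode)
    if spectral_stability_margin(A, mode) <= 0:
        return 0.0
    n = A.shape[0]
    I = np.eye(n)

    if mode is TimeMode.CONTINUOUS:
        w_max = 3.0 * max(float(np.linalg.norm(A, 2)), 1e-12)

        def f(w: float) -> float:
            return float(np.linalg.svd(A - 1j * w * I, compute_uv=False)[-1])

        grid = np.linspace(-w_max, w_max, n_grid)
    else:

        def f(t: float) -> float:
            return float(np.linalg.svd(A - np.exp(1j * t) * I, compute_uv=False)[-1])

        grid = np.linspace(0.0, 2.0 * np.pi, n_grid, endpoint=False)

    vals = np.array([f(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, n_grid - 1)]
    res = minimize_scalar(f, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(min(vals[k], res.fun))


# ---------------------------------------------------------------------------
# Gramian and energy
# ---------------------------------------------------------------------------


def controllability_gramian(net: LinearNetwork) -> GramianReport:
    """Infinite-horizon controllability Gramian of a stable driven network.

    Solves the Lyapunov equation ``A G + G A^T + B B^T = 0`` (continuous)
    or the Stein equation ``A G A^T - G + B B^T = 0`` (discrete).  The
    Gramian is symmetrized before reporting and the report carries the
    residual of the defining equation.
    """
    if net.n_c == 0:
        raise ValueError("Gramian requires at least one driver node")
    A = net.A
    s = spectral_stability_margin(A, net.time_mode)
    if s <= 0:
        raise StabilityError(
            f"network is unstable (stability margin s(A) = {s:.6g}); "
            "the Gramian integral diverges")
    B = net.B
    Q = B @ B.T
    if net.time_mode is TimeMode.CONTINUOUS:
        G = sla.solve_continuous_lyapunov(A, -Q)
        residual = float(np.linalg.norm(A @ G + G @ A.T + Q, "fro"))
    else:
        G = sla.solve_discrete_lyapunov(A, Q)
        residual = float(np.linalg.norm(A @ G @ A.T - G + Q, "fro"))
    G = 0.5 * (G + G.T)
    evals = np.linalg.eigvalsh(G)
    trace = float(np.trace(G))
    return GramianReport(
        G=G,
        sigma_bar=trace / net.n,
        trace=trace,
        min_eig=float(evals[0]),
        residual=residual,
        singular_values=np.abs(evals)[::-1],
    )


def min_control_energy(report: GramianReport, x_f, rtol: float = 1e-10) -> float:
    """Minimum input energy ``x_f^T G^{-1} x_f`` to steer the state from the
    origin to ``x_f``; requires an invertible Gramian (controllability)."""
    x_f = np.asarray(x_f, dtype=float)
    G = report.G
    if report.min_eig <= rtol * max(1.0, report.trace):
        raise ControllabilityError(
            "Gramian is singular to working precision: network not controllable")
    y = sla.solve(G, x_f, assume_a="pos")
    return float(max(x_f @ y, 0.0))


# ---------------------------------------------------------------------------
# full reports and bounds
# ---------------------------------------------------------------------------


def fragility_report(A, time_mode: TimeMode = TimeMode.CONTINUOUS,
                     tol: float = 1e-6) -> FragilityReport:
    """Compute r, s, kappa(V) and the non-normality degree in one pass."""
    A = _check_square(A)
    mode = TimeMode(time_mode)
    return FragilityReport(
        r=stability_radius(A, mode, tol),
        s=spectral_stability_margin(A, mode),
        kappa_V=eigvec_condition(A),
        non_normality=non_normality(A),
        eigenvalues=np.linalg.eigvals(A),
        tol=tol,
    )


def evaluate_bounds(net: LinearNetwork, frag: FragilityReport,
                    gram: GramianReport) -> BoundReport:
    """Evaluate every applicable responsiveness upper bound on one network.

    The bounds tie ``sigma_bar(G)`` to the stability radius r, the margin
    s, the driver fraction n_c/n, the asymmetry ``||A - A^T||`` and the
    eigenvector conditioning kappa(V):

    * general:        (n_c/n) (1 + 4||A-A^T||/(3 pi r)) (1/r)
    * symmetric:      (n_c/n) / r
    * diagonalizable: (n_c/n) kappa^2(V) / (2 s)
    * normal:         (n_c/n) / (2 r)

    All four are theorems for stable continuous-time networks, so every
    applicable ratio ``sigma_bar/rhs`` is at most 1 (up to roundoff).
    Also checks the sandwich ``s/kappa <= r <= s``.
    """
    if net.time_mode is not TimeMode.CONTINUOUS:
        raise ValueError("the tradeoff bounds are stated for continuous-time "
                         "networks; discrete-time analogues differ")
    r, s, kappa = frag.r, frag.s, frag.kappa_V
    if r <= 0:
        raise StabilityError("bounds require a stable network (r > 0)")
    frac = net.n_c / net.n
    nn = frag.non_normality

    sym = is_symmetric(net.A)
    normal = is_normal(net.A)
    diagonalizable = math.isfinite(kappa)

    rhs_general = frac * (1.0 + 4.0 * nn / (3.0 * math.pi * r)) / r
    rhs_symmetric = frac / r if sym else math.nan
    rhs_diag = frac * kappa ** 2 / (2.0 * s) if diagonalizable else math.nan
    rhs_normal = frac / (2.0 * r) if normal else math.nan

    sb = gram.sigma_bar

    def ratio(rhs: float) -> float:
        return sb / rhs if math.isfinite(rhs) else math.nan

    tol = frag.tol + 1e-9 * max(1.0, s)
    sandwich = r <= s + tol
    if diagonalizable:
        sandwich = sandwich and (s / kappa - tol <= r)

    return BoundReport(
        sigma_bar=sb,
        rhs_general=rhs_general,
        rhs_symmetric=rhs_symmetric,
        rhs_diagonalizable=rhs_diag,
        rhs_normal=rhs_normal,
        ratio_general=ratio(rhs_general),
        ratio_symmetric=ratio(rhs_symmetric),
        ratio_diagonalizable=ratio(rhs_diag),
        ratio_normal=ratio(rhs_normal),
        is_symmetric=sym,
        is_normal=normal,
        is_diagonalizable=diagonalizable,
        sandwich_ok=bool(sandwich),
    )
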