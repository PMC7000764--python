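"""Synthetic network families for fragility/responsiveness experiments.

Each factory returns a :class:`~fragnet.network.LinearNetwork` (driven at
every node by default; use ``with_drivers`` to restrict) and records its
construction parameters in ``net.meta``.  All randomness flows through a
``seed`` argument, so identical arguments reproduce identical matrices.

Families
--------
bounded_degree_network
    Random d-regular digraph, U[w_lo, w_hi] weights, diagonal-stabilized.
skew_normal_family
    ``A_skew - alpha I`` with A_skew skew-symmetric: normal, stable, and
    with stability margin and radius both exactly alpha.
nonnormal_family
    Diagonal similarity ``D^{-1} A_sym D`` with ``D = diag(1, b, b^2, ...)``:
    the spectrum of a stable symmetric matrix, but non-normality that grows
    with the base b.
lqr_family
    Closed loop of an infinite-horizon LQR design (Q = I, R = gamma I,
    B = I) around a random symmetric plant; gamma prices the control effort.
platoon_linearization
    Optimal-velocity car-following platoon linearized at the uniform-flow
    equilibrium.
wave_discretization
    Discrete-time matrix from a space-time discretization of the one-way
    wave equation du/dt = du/dx.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .network import LinearNetwork, TimeMode, all_drivers

__all__ = [
    "GeneratorSpec",
    "generate",
    "bounded_degree_network",
    "skew_normal_family",
    "nonnormal_family",
    "lqr_family",
    "lqr_closed_loop",
    "platoon_linearization",
    "CarFollowingParams",
    "wave_discretization",
]


def _stabilize(A: np.ndarray, margin: float) -> np.ndarray:
    """Shift the diagonal so the continuous-time stability margin equals
    ``margin`` exactly (up to eigenvalue roundoff)."""
    shift = np.max(np.linalg.eigvals(A).real) + margin
    return A - shift * np.eye(A.shape[0])


# ---------------------------------------------------------------------------
# bounded-degree random digraphs
# ---------------------------------------------------------------------------


def _random_regular_digraph(n: int, d: int, rng: np.random.Generator,
                            max_tries: int = 1000) -> np.ndarray:
    """0/1 adjacency of a random digraph with all in- and out-degrees equal
    to d, no self-loops, no parallel edges.

    Configuration-model pairing of in/out stubs, then random 2-swaps to
    repair self-loops and duplicate edges; a swap is committed only when
    both replacement edges are admissible, so the defect count never grows.
    """
    from collections import Counter

    sources = np.repeat(np.arange(n), d)
    m = len(sources)
    for _ in range(max_tries):
        targets = rng.permutation(sources)
        counts = Counter(zip(sources.tolist(), targets.tolist()))

        def is_bad(i: int) -> bool:
            e = (sources[i], targets[i])
            return e[0] == e[1] or counts[e] > 1

        bad = [i for i in range(m) if is_bad(i)]
        budget = 500 * max(len(bad), 1)
        while bad and budget > 0:
            budget -= 1
            i = bad[-1]
            if not is_bad(i):
                bad.pop()
                continue
            j = int(rng.integers(m))
            if j == i:
                continue
            si, ti = int(sources[i]), int(targets[i])
            sj, tj = int(sources[j]), int(targets[j])
            new_i, new_j = (si, tj), (sj, ti)
            if si == tj or sj == ti or new_i == new_j:
                continue
            # admissible only if neither replacement collides with an edge
            # other than the two being removed
            if counts[new_i] - (new_i == (sj, tj)) > 0:
                continue
            if counts[new_j] - (new_j == (si, ti)) > 0:
                continue
            counts[(si, ti)] -= 1
            counts[(sj, tj)] -= 1
            counts[new_i] += 1
            counts[new_j] += 1
            targets[i], targets[j] = tj, ti
            bad.pop()
            if is_bad(j):
                bad.append(j)
        if not bad:
            M = np.zeros((n, n))
            M[targets, sources] = 1.0  # edge source -> target acts on row target
            return M
    raise RuntimeError(
        f"could not realize a {d}-regular digraph on {n} nodes "
        f"after {max_tries} attempts")


def bounded_degree_network(n: int, d: int, w_lo: float = 0.0, w_hi: float = 1.0,
                           margin_law: tuple[float, float] = (0.1, 1.0),
                           seed: int | None = None) -> LinearNetwork:
    """Random d-regular digraph with U[w_lo, w_hi] weights, stabilized by a
    diagonal shift to a margin drawn uniformly from ``margin_law``.

    The bounded in- and out-degrees keep ``||A - A^T||`` bounded via
    ``||A - A^T|| <= 2 sqrt(||A||_1 ||A^T||_1)``, which makes the general
    tradeoff bound informative as n grows.
    """
    if not 0 <= d < n:
        raise ValueError(f"need 0 <= d < n, got d={d}, n={n}")
    if w_lo >= w_hi:
        raise ValueError("w_lo must be < w_hi")
    rng = np.random.default_rng(seed)
    if d == 0:
        A = np.zeros((n, n))
    else:
        A = _random_regular_digraph(n, d, rng)
        A *= rng.uniform(w_lo, w_hi, size=(n, n))
    m = rng.uniform(*margin_law)
    A = _stabilize(A, m)
    return all_drivers(A, meta={"family": "bounded_degree", "n": n, "d": d,
                                "margin": m, "seed": seed})


# ---------------------------------------------------------------------------
# normal / non-normal parametric families
# ---------------------------------------------------------------------------


def skew_normal_family(n: int, alpha: float, seed: int | None = None) -> LinearNetwork:
    """``A = A_skew - alpha I`` with a random skew-symmetric A_skew.

    Always normal (purely imaginary skew spectrum shifted left by alpha),
    always stable, with ``s(A) = r(A) = alpha`` and the closed-form
    responsiveness ``sigma_bar(G) = n_c / (2 alpha n)`` for any driver set.
    """
    if alpha <= 0:
        raise ValueError(f"alpha must be positive, got {alpha}")
    rng = np.random.default_rng(seed)
    T = np.triu(rng.standard_normal((n, n)), k=1)
    A = T - T.T - alpha * np.eye(n)
    return all_drivers(A, meta={"family": "skew_normal", "n": n,
                                "alpha": alpha, "seed": seed})


def nonnormal_family(n: int, beta: float, seed: int | None = None,
                     margin_law: tuple[float, float] = (0.5, 1.5)) -> LinearNetwork:
    """Diagonal conjugation ``D^{-1} A_sym D`` of a stable random symmetric
    matrix, with ``D = diag(1, beta, beta^2, ..., beta^{n-1})``.

    The spectrum (hence the margin s) is that of A_sym for every beta,
    while the eigenvector conditioning kappa(V) — and with it the gap
    between r and s — grows with beta.  ``beta = 1`` is allowed as the
    symmetric limit.
    """
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, n))
    Asym = _stabilize(0.5 * (M + M.T), rng.uniform(*margin_law))
    powers = np.arange(n, dtype=float)
    # (D^{-1} A D)[i, j] = A[i, j] * beta^(j - i)
    A = Asym * beta ** (powers[None, :] - powers[:, None])
    return all_drivers(A, meta={"family": "nonnormal_beta", "n": n,
                                "beta": beta, "seed": seed})


def lqr_family(n: int, gamma: float, seed: int | None = None) -> LinearNetwork:
    """Optimal LQR closed loop ``A + B K_gamma`` for a random symmetric
    plant, with B = I, state cost Q = I and input cost R = gamma I.

    ``K_gamma = -R^{-1} B^T P`` where P solves the continuous algebraic
    Riccati equation; the closed loop is stable for every gamma >= 1, and
    larger gamma (more expensive control) yields a lazier, less responsive
    but more robust loop.
    """
    if gamma < 1:
        raise ValueError(f"gamma must be >= 1, got {gamma}")
    rng = np.random.default_rng(seed)
    M = rng.standard_normal((n, n))
    A = 0.5 * (M + M.T)
    try:
        closed = lqr_closed_loop(A, gamma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise RuntimeError(f"Riccati solve failed for seed={seed}") from exc
    return all_drivers(closed, meta={"family": "lqr_gamma", "n": n,
                                     "gamma": gamma, "seed": seed})


def lqr_closed_loop(A: np.ndarray, gamma: float) -> np.ndarray:
    """``A + B K`` for the LQR gain ``K = -R^{-1} B^T P`` with B = I,
    Q = I, R = gamma I, where P solves the continuous algebraic Riccati
    equation ``A^T P + P A - P B R^{-1} B^T P + Q = 0``."""
    A = np.asarray(A, dtype=float)
    n = A.shape[0]
    P = sla.solve_continuous_are(A, np.eye(n), np.eye(n), gamma * np.eye(n))
    return A - P / gamma


# ---------------------------------------------------------------------------
# vehicle platoon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CarFollowingParams:
    """Optimal-velocity car-following parameters.

    ``accel`` is the driver relaxation rate (1/s), ``v_max`` the free-flow
    speed and ``h_c`` the inflection headway of the optimal-velocity
    function ``V(h) = v_max (tanh(h - h_c) + tanh(h_c)) / (1 + tanh(h_c))``.
    """

    accel: float = 1.0
    v_max: float = 2.0
    h_c: float = 2.0

    def v_opt(self, h: float) -> float:
        th = math.tanh(self.h_c)
        return self.v_max * (math.tanh(h - self.h_c) + th) / (1.0 + th)

    def v_opt_prime(self, h: float) -> float:
        th = math.tanh(self.h_c)
        return self.v_max / math.cosh(h - self.h_c) ** 2 / (1.0 + th)

    def equilibrium_headway(self, velocity: float) -> float:
        """Solve ``V(h*) = velocity``; defined for 0 < velocity < v_max."""
        th = math.tanh(self.h_c)
        z = velocity * (1.0 + th) / self.v_max - th
        if not -1.0 < z < 1.0:
            raise ValueError(
                f"velocity {velocity} outside the range (0, {self.v_max}) "
                "of the optimal-velocity function")
        return self.h_c + math.atanh(z)


def platoon_linearization(n_followers: int, velocity: float,
                          car_params: CarFollowingParams | None = None
                          ) -> LinearNetwork:
    """Linearized platoon of ``n_followers`` vehicles behind a leader moving
    at constant ``velocity``.

    Each follower obeys the optimal-velocity model ``dv_i/dt =
    a (V(h_i) - v_i)``, ``dh_i/dt = v_{i-1} - v_i``; at equilibrium all
    vehicles share the leader speed and the headway h* with V(h*) =
    velocity.  The state is the stack of (headway, velocity) deviations, so
    the network has ``2 n_followers`` nodes.  Higher leader speed pushes h*
    into the flat tail of V, shrinking V'(h*) and dragging an eigenvalue
    toward zero: the platoon becomes both more fragile and more responsive.
    """
    if n_followers < 1:
        raise ValueError("need at least one follower")
    p = car_params or CarFollowingParams()
    h_star = p.equilibrium_headway(velocity)
    vp = p.v_opt_prime(h_star)
    a = p.accel
    N = n_followers
    A = np.zeros((2 * N, 2 * N))
    for i in range(N):
        ih, iv = 2 * i, 2 * i + 1
        A[ih, iv] = -1.0          # dh_i/dt loses own speed
        if i > 0:
            A[ih, iv - 2] = 1.0   # and gains the predecessor's
        A[iv, ih] = a * vp
        A[iv, iv] = -a
    return all_drivers(A, meta={"family": "platoon", "n_followers": N,
                                "velocity": velocity, "h_star": h_star,
                                "v_prime": vp})


# ---------------------------------------------------------------------------
# wave-equation discretization (discrete time)
# ---------------------------------------------------------------------------


def wave_discretization(n_x: int, delta: float, scheme: str = "upwind",
                        boundary: str = "zero_inflow") -> LinearNetwork:
    """Discrete-time matrix for the one-way wave equation du/dt = du/dx on
    x in (-1, 1), with time step ``dt = delta * dx``.

    The default first-order upwind stencil ``u_i+ = (1 - delta) u_i +
    delta u_{i+1}`` with zero inflow at the right boundary gives an
    upper-bidiagonal matrix with spectral radius ``1 - delta``; ``delta =
    1`` is the exact-shift (nilpotent) limit.  A Lax-Wendroff stencil is
    available as an alternative scheme; ``boundary`` may be
    ``zero_inflow`` or ``periodic``.
    """
    if n_x < 3:
        raise ValueError("need at least 3 interior grid points")
    if not 0 < delta <= 1:
        raise ValueError(f"CFL violation: need 0 < delta <= 1, got {delta}")
    n = n_x
    A = np.zeros((n, n))
    if scheme == "upwind":
        for i in range(n):
            A[i, i] = 1.0 - delta
            if i + 1 < n:
                A[i, i + 1] = delta
            elif boundary == "periodic":
                A[i, 0] = delta
    elif scheme == "lax_wendroff":
        c0 = 1.0 - delta ** 2
        cp = 0.5 * delta * (delta + 1.0)   # coefficient of u_{i+1}
        cm = 0.5 * delta * (delta - 1.0)   # coefficient of u_{i-1}
        for i in range(n):
            A[i, i] = c0
            if i + 1 < n:
                A[i, i + 1] = cp
            elif boundary == "periodic":
                A[i, 0] = cp
            if i - 1 >= 0:
                A[i, i - 1] = cm
            elif boundary == "periodic":
                A[i, n - 1] = cm
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    sv = np.linalg.svd(A, compute_uv=False)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else math.inf
    return all_drivers(A, TimeMode.DISCRETE,
                       meta={"family": "wave", "n_x": n_x, "delta": delta,
                             "scheme": scheme, "boundary": boundary,
                             "condition_number": cond})


# ---------------------------------------------------------------------------
# declarative dispatch
# ---------------------------------------------------------------------------

_FAMILIES = {
    "bounded_degree": bounded_degree_network,
    "skew_normal": skew_normal_family,
    "nonnormal_beta": nonnormal_family,
    "lqr_gamma": lqr_family,
    "platoon": platoon_linearization,
    "wave": wave_discretization,
}


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative recipe (family, size, parameters, seed) for a network.

    ``generate(spec)`` is deterministic: equal specs give bitwise-equal
    matrices.
    """

    family: str
    n: int
    params: dict = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES and self.family != "mutualistic_glv":
            raise ValueError(f"unknown family {self.family!r}; "
                             f"choose from {sorted(_FAMILIES)} or mutualistic_glv")


def generate(spec: GeneratorSpec) -> LinearNetwork:
    """Build the network described by ``spec``."""
    if spec.family == "mutualistic_glv":
        from .glv import mutualistic_glv
        model = mutualistic_glv(spec.n, seed=spec.seed, **spec.params)
        return model.network()
    if spec.family == "platoon":
        return platoon_linearization(spec.n, **spec.params)
    if spec.family == "wave":
        return wave_discretization(spec.n, **spec.params)
    return _FAMILIES[spec.family](spec.n, seed=spec.seed, **spec.params)
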