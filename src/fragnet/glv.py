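"""Mutualistic generalized Lotka-Volterra (GLV) communities.

Species abundances evolve as

    dx_i/dt = x_i ( r_i - s_i x_i + sum_{j != i} g_ij x_j ),

with intrinsic growth r_i > 0, self-limitation s_i > 0 and nonnegative
mutualistic interactions g_ij supported on a small-world (Watts-Strogatz)
topology.  The coexistence equilibrium solves the linear system
``(diag(s) - G) x* = r``; it is feasible when every component of x* is
positive, and its local stability is governed by the Jacobian
``J = diag(x*) (G - diag(s))``.

This is a deliberately generic mutualistic community model: it reproduces
the qualitative phenomenology of interest (feasible small communities,
stability probability decaying with richness, species loss after
perturbations of unstable equilibria) without committing to any particular
saturating functional response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .network import LinearNetwork, all_drivers

__all__ = ["GLVModel", "GLVTrajectory", "mutualistic_glv", "simulate_glv"]


@dataclass(frozen=True)
class GLVModel:
    """A mutualistic GLV community with its equilibrium and linearization.

    ``equilibrium`` and ``jacobian`` are ``None`` when the coexistence
    equilibrium is infeasible (some component nonpositive) — that is a
    result, not an error.
    """

    growth: np.ndarray
    self_reg: np.ndarray
    interactions: np.ndarray
    equilibrium: np.ndarray | None
    jacobian: np.ndarray | None
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def n(self) -> int:
        return self.growth.shape[0]

    @property
    def feasible(self) -> bool:
        return self.equilibrium is not None

    @property
    def stable(self) -> bool:
        """Feasible and locally stable at the coexistence equilibrium."""
        if not self.feasible:
            return False
        return float(np.max(np.linalg.eigvals(self.jacobian).real)) < 0

    def rhs(self, x: np.ndarray) -> np.ndarray:
        """Right-hand side of the GLV ODE at abundances x."""
        return x * (self.growth - self.self_reg * x + self.interactions @ x)

    def network(self) -> LinearNetwork:
        """Jacobian at equilibrium as a fully driven linear network."""
        if not self.feasible:
            raise ValueError("infeasible equilibrium: no linearization")
        return all_drivers(self.jacobian, meta=dict(self.meta))

    def with_interactions(self, interactions: np.ndarray) -> "GLVModel":
        """Same rates, new interaction matrix; equilibrium recomputed."""
        return _assemble(self.growth, self.self_reg, interactions,
                         dict(self.meta))


def _assemble(growth, self_reg, interactions, meta) -> GLVModel:
    n = growth.shape[0]
    M = np.diag(self_reg) - interactions
    try:
        x_star = np.linalg.solve(M, growth)
    except np.linalg.LinAlgError:
        x_star = None
    if x_star is None or not np.all(x_star > 0) or not np.all(np.isfinite(x_star)):
        return GLVModel(growth, self_reg, interactions, None, None, meta)
    jac = x_star[:, None] * (interactions - np.diag(self_reg))
    return GLVModel(growth, self_reg, interactions, x_star, jac, meta)


def mutualistic_glv(n: int, k: int = 4, p: float = 0.3,
                    gamma_max: float = 0.7,
                    growth_range: tuple[float, float] = (0.5, 1.0),
                    self_reg_range: tuple[float, float] = (1.0, 2.0),
                    seed: int | None = None) -> GLVModel:
    """Draw a random mutualistic community on a small-world topology.

    Parameters
    ----------
    n:
        Species count.
    k, p:
        Watts-Strogatz ring degree (even, < n) and rewiring probability.
    gamma_max:
        Interaction weights are i.i.d. U[0, gamma_max] on each directed
        edge of the (symmetric) small-world support.  The default 0.7
        makes a species' expected mutualistic input (~ k gamma_max / 2 =
        1.4) comparable to its self-limitation (U[1, 2]), placing
        communities at the feasibility/stability boundary: small
        communities are usually stable while the stability probability
        decays toward zero with species richness.
    growth_range, self_reg_range:
        Uniform ranges for r_i and s_i.
    """
    if k % 2 != 0 or not 0 < k < n:
        raise ValueError(f"k must be even with 0 < k < n, got k={k}, n={n}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {p}")
    if gamma_max < 0:
        raise ValueError("gamma_max must be nonnegative")
    rng = np.random.default_rng(seed)
    graph_seed = int(rng.integers(2 ** 31 - 1))
    support = nx.watts_strogatz_graph(n, k, p, seed=graph_seed)
    G = np.zeros((n, n))
    for i, j in support.edges:
        G[i, j] = rng.uniform(0.0, gamma_max)
        G[j, i] = rng.uniform(0.0, gamma_max)
    growth = rng.uniform(*growth_range, size=n)
    self_reg = rng.uniform(*self_reg_range, size=n)
    meta = {"family": "mutualistic_glv", "n": n, "k": k, "p": p,
            "gamma_max": gamma_max, "seed": seed}
    return _assemble(growth, self_reg, G, meta)


@dataclass
class GLVTrajectory:
    """Sampled GLV trajectory with an escape flag for diverging dynamics."""

    t: np.ndarray
    x: np.ndarray  # shape (len(t), n)
    escaped: bool

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (time, node, value)."""
        n = self.x.shape[1]
        return pd.DataFrame({
            "time": np.repeat(self.t, n),
            "node": np.tile(np.arange(n), len(self.t)),
            "value": self.x.ravel(),
        })


_ESCAPE_NORM = 1e6


def simulate_glv(model: GLVModel, x0, horizon: float,
                 perturbation: tuple[float, np.ndarray] | None = None,
                 n_samples: int = 400, rtol: float = 1e-8,
                 atol: float = 1e-10) -> GLVTrajectory:
    """Integrate the GLV dynamics, optionally kicking the state at one time.

    ``perturbation = (t_p, v)`` adds the vector v to the state at time t_p
    (the Fig.-2-style protocol: sit at equilibrium, then nudge).  Diverging
    trajectories (state norm beyond 1e6) are truncated and flagged
    ``escaped`` rather than raising — an expected outcome for unstable
    equilibria.  Abundances are clipped at zero within solver tolerance.
    """
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 < 0):
        raise ValueError("initial abundances must be nonnegative")

    def rhs(_t, x):
        return model.rhs(x)

    def escape(_t, x):
        return float(np.linalg.norm(x) - _ESCAPE_NORM)

    escape.terminal = True
    escape.direction = 1.0

    segments: list[tuple[float, float, np.ndarray | None]] = [(0.0, horizon, None)]
    if perturbation is not None:
        t_p, v = perturbation
        if not 0.0 < t_p < horizon:
            raise ValueError("perturbation time must lie inside (0, horizon)")
        segments = [(0.0, t_p, None), (t_p, horizon, np.asarray(v, dtype=float))]

    ts, xs = [], []
    escaped = False
    state = x0
    for start, stop, kick in segments:
        if kick is not None:
            state = state + kick
        t_eval = np.linspace(start, stop, max(int(n_samples * (stop - start)
                                                  / horizon), 2))
        sol = solve_ivp(rhs, (start, stop), state, t_eval=t_eval,
                        events=escape, rtol=rtol, atol=atol, method="LSODA")
        ts.append(sol.t)
        xs.append(np.clip(sol.y.T, 0.0, None))
        state = sol.y[:, -1] if sol.y.size else state
        if sol.status == 1:  # escape event fired
            escaped = True
            break
    return GLVTrajectory(np.concatenate(ts), np.vstack(xs), escaped)
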