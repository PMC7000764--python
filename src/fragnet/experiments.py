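"""Sweep orchestration: tidy result tables with bound certificates.

Each sweep emits one :class:`pandas.DataFrame` row per realization,
carrying the fragility/responsiveness metrics, every applicable bound
right-hand side and ratio, and the provenance columns (family, swept
parameter, seed, replicate).  A sweep is reproducible from its arguments:
the same configuration and seed give the same table.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .generators import (bounded_degree_network, lqr_family, nonnormal_family,
                         platoon_linearization, skew_normal_family,
                         wave_discretization)
from .glv import mutualistic_glv
from .metrics import (controllability_gramian, evaluate_bounds,
                      fragility_report, spectral_stability_margin)
from .network import LinearNetwork, TimeMode

__all__ = ["measure_network", "sweep_drivers", "sweep_size",
           "sweep_parameter", "stability_probability_curve"]


def measure_network(net: LinearNetwork, radius_tol: float = 1e-6) -> dict:
    """All metrics (and, for continuous stable nets, all bound ratios) of a
    single network, as one flat record."""
    frag = fragility_report(net.A, net.time_mode, radius_tol)
    rec = {
        "n": net.n, "n_c": net.n_c,
        "r": frag.r, "s": frag.s, "kappa_V": frag.kappa_V,
        "non_normality": frag.non_normality,
        "sigma_bar": math.nan,
        "rhs_general": math.nan, "rhs_symmetric": math.nan,
        "rhs_diagonalizable": math.nan, "rhs_normal": math.nan,
        "ratio_general": math.nan, "ratio_symmetric": math.nan,
        "ratio_diagonalizable": math.nan, "ratio_normal": math.nan,
        "sandwich_ok": True,
        "stable": frag.s > 0,
    }
    if frag.s > 0:
        gram = controllability_gramian(net)
        rec["sigma_bar"] = gram.sigma_bar
        if net.time_mode is TimeMode.CONTINUOUS:
            bounds = evaluate_bounds(net, frag, gram)
            rec.update({k: getattr(bounds, k) for k in (
                "rhs_general", "rhs_symmetric", "rhs_diagonalizable",
                "rhs_normal", "ratio_general", "ratio_symmetric",
                "ratio_diagonalizable", "ratio_normal", "sandwich_ok")})
    return rec


def sweep_drivers(net: LinearNetwork, nc_values: Sequence[int],
                  reps_per_nc: int = 50, seed: int | None = None
                  ) -> pd.DataFrame:
    """Responsiveness versus number of drivers, on one fixed stable matrix.

    For each n_c, draws ``reps_per_nc`` random driver subsets and records
    ``sigma_bar(G)``.  Because the Gramian trace is additive over driver
    columns, the per-n_c means lie on a line through the origin.
    When ``n_c = n`` there is a single subset, so one deterministic record
    is emitted.
    """
    A = net.A
    if spectral_stability_margin(A, net.time_mode) <= 0:
        raise ValueError("driver sweep requires a stable matrix")
    n = A.shape[0]
    rng = np.random.default_rng(seed)
    rows = []
    for nc in nc_values:
        if not 1 <= nc <= n:
            raise ValueError(f"n_c must be in [1, {n}], got {nc}")
        reps = 1 if nc == n else reps_per_nc
        for rep in range(reps):
            drivers = rng.choice(n, size=nc, replace=False)
            sub = net.with_drivers(sorted(int(d) for d in drivers))
            gram = controllability_gramian(sub)
            rows.append({"family": "fixed_matrix", "param_name": "n_c",
                         "param_value": nc, "n": n, "n_c": nc,
                         "sigma_bar": gram.sigma_bar, "replicate": rep,
                         "seed": seed})
    return pd.DataFrame(rows)


def sweep_size(n_values: Sequence[int], d: int = 6, n_c: int = 20,
               reps: int = 100, seed: int | None = None,
               fixed_margin: float | None = None,
               radius_tol: float = 1e-6) -> pd.DataFrame:
    """Fragility/responsiveness across network sizes at fixed driver count.

    For each n, generates ``reps`` bounded-degree networks (degree d,
    U[0, 1] weights, diagonal-stabilized) and records (r, sigma_bar) with
    ``n_c`` randomly chosen drivers.  Passing ``fixed_margin`` pins the
    stabilization margin — the constant-fragility regime, in which the
    median responsiveness must fall as n grows.
    """
    if n_c > min(n_values) or d >= min(n_values):
        raise ValueError("n_c and d must not exceed the smallest n")
    rng = np.random.default_rng(seed)
    margin_law = ((fixed_margin, fixed_margin) if fixed_margin is not None
                  else (0.1, 1.0))
    rows = []
    for n in n_values:
        for rep in range(reps):
            gseed = int(rng.integers(2 ** 31 - 1))
            net = bounded_degree_network(n, d, margin_law=margin_law,
                                         seed=gseed)
            drivers = rng.choice(n, size=n_c, replace=False)
            net = net.with_drivers(sorted(int(x) for x in drivers))
            rec = measure_network(net, radius_tol)
            rec.update({"family": "bounded_degree", "param_name": "n",
                        "param_value": n, "replicate": rep, "seed": gseed})
            rows.append(rec)
    return pd.DataFrame(rows)


def _build_family(family: str, value: float, n: int, seed: int
                  ) -> LinearNetwork:
    if family == "skew_normal":
        return skew_normal_family(n, alpha=value, seed=seed)
    if family == "nonnormal_beta":
        return nonnormal_family(n, beta=value, seed=seed)
    if family == "lqr_gamma":
        return lqr_family(n, gamma=value, seed=seed)
    if family == "platoon":
        return platoon_linearization(n, velocity=value)
    if family == "wave":
        return wave_discretization(n, delta=value)
    raise ValueError(f"unknown sweep family {family!r}")


_PARAM_NAMES = {"skew_normal": "alpha", "nonnormal_beta": "beta",
                "lqr_gamma": "gamma", "platoon": "velocity", "wave": "delta"}


def sweep_parameter(family: str, param_grid: Iterable[float], n: int = 40,
                    reps: int = 10, seed: int | None = None,
                    radius_tol: float = 1e-6) -> pd.DataFrame:
    """Metric sweep over a family parameter with every node driven.

    Families: ``skew_normal`` (alpha, the stability margin),
    ``nonnormal_beta`` (beta, the non-normality base), ``lqr_gamma``
    (gamma, the control cost), ``platoon`` (leader velocity; ``n`` is the
    follower count and the platoon is deterministic, so replicates
    coincide) and ``wave`` (delta, the time/space-step ratio; discrete
    time).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for value in param_grid:
        rep_seeds = rng.integers(2 ** 31 - 1, size=reps)
        for rep, rseed in enumerate(rep_seeds):
            net = _build_family(family, float(value), n, int(rseed))
            rec = measure_network(net, radius_tol)
            rec.update({"family": family,
                        "param_name": _PARAM_NAMES[family],
                        "param_value": float(value), "replicate": rep,
                        "seed": int(rseed)})
            rows.append(rec)
    return pd.DataFrame(rows)


def stability_probability_curve(n_values: Sequence[int], trials: int = 500,
                                glv_config: dict | None = None,
                                seed: int | None = None) -> pd.DataFrame:
    """Fraction of random mutualistic communities that are feasible and
    stable, per community size, with binomial standard errors."""
    if trials < 1:
        raise ValueError("need at least one trial")
    cfg = glv_config or {}
    rng = np.random.default_rng(seed)
    rows = []
    for n in n_values:
        draws = rng.integers(2 ** 31 - 1, size=trials)
        stable = sum(mutualistic_glv(n, seed=int(s), **cfg).stable
                     for s in draws)
        frac = stable / trials
        rows.append({"n": n, "trials": trials, "n_stable": stable,
                     "fraction_stable": frac,
                     "stderr": math.sqrt(frac * (1.0 - frac) / trials),
                     "seed": seed})
    return pd.DataFrame(rows)
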