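"""Result containers for fragility, responsiveness and bound evaluation."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict, field

import numpy as np


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, float) and math.isnan(x):
        return None
    return x


@dataclass
class FragilityReport:
    """Spectral and perturbation-based stability diagnostics of a matrix.

    Attributes
    ----------
    r:
        Stability radius: the 2-norm of the smallest complex matrix
        perturbation that destabilizes A.  Zero for an unstable matrix.
        The network fragility is ``1/r``.
    s:
        Stability margin: distance of the spectrum from the stability
        boundary (imaginary axis, or unit circle in discrete time).
        Negative when unstable.
    kappa_V:
        2-norm condition number of the unit-column eigenvector matrix;
        ``nan`` when the matrix is numerically defective.
    non_normality:
        Spectral norm of ``A - A^T``, the asymmetry / non-normality degree.
    eigenvalues:
        Spectrum of A.
    tol:
        Absolute tolerance used by the stability-radius bisection.
    """

    r: float
    s: float
    kappa_V: float
    non_normality: float
    eigenvalues: np.ndarray
    tol: float

    @property
    def fragility(self) -> float:
        return math.inf if self.r == 0 else 1.0 / self.r

    @property
    def stable(self) -> bool:
        return self.s > 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: _jsonable(v) for k, v in d.items()}


@dataclass
class GramianReport:
    """Controllability Gramian of a stable driven network.

    ``G`` solves ``A G + G A^T + B B^T = 0`` (continuous) or
    ``A G A^T - G + B B^T = 0`` (discrete); ``sigma_bar`` — the average
    singular value of G, equal to ``trace(G)/n`` since G is PSD — is the
    network responsiveness metric.
    """

    G: np.ndarray
    sigma_bar: float
    trace: float
    min_eig: float
    residual: float
    singular_values: np.ndarray = field(default=None)

    def to_dict(self, include_matrix: bool = False) -> dict:
        d = {
            "sigma_bar": _jsonable(self.sigma_bar),
            "trace": _jsonable(self.trace),
            "min_eig": _jsonable(self.min_eig),
            "residual": _jsonable(self.residual),
        }
        if include_matrix:
            d["G"] = _jsonable(self.G)
        return d


@dataclass
class BoundReport:
    """Evaluated right-hand sides of the responsiveness upper bounds.

    ``rhs_general`` is the bound valid for every stable network,
    (n_c/n) (1 + 4||A - A^T|| / (3 pi r)) / r.  ``rhs_symmetric``
    ((n_c/n)/r), ``rhs_diagonalizable`` ((n_c/n) kappa^2/(2 s)) and
    ``rhs_normal`` ((n_c/n)/(2 r)) apply only when the corresponding
    structure flag is set; inapplicable entries are ``nan``.  Each ratio is
    ``sigma_bar / rhs`` and is provably at most 1 where applicable.
    """

    sigma_bar: float
    rhs_general: float
    rhs_symmetric: float
    rhs_diagonalizable: float
    rhs_normal: float
    ratio_general: float
    ratio_symmetric: float
    ratio_diagonalizable: float
    ratio_normal: float
    is_symmetric: bool
    is_normal: bool
    is_diagonalizable: bool
    sandwich_ok: bool

    def applicable_ratios(self) -> dict[str, float]:
        out = {"general": self.ratio_general}
        if self.is_symmetric:
            out["symmetric"] = self.ratio_symmetric
        if self.is_diagonalizable:
            out["diagonalizable"] = self.ratio_diagonalizable
        if self.is_normal:
            out["normal"] = self.ratio_normal
        return out

    def to_dict(self) -> dict:
        return {k: _jsonable(v) for k, v in asdict(self).items()}


def write_json_report(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump({k: _jsonable(v) for k, v in payload.items()}, fh, indent=2)
        fh.write("\n")
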