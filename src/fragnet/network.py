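"""Linear dynamic network container.

A network is a directed weighted graph whose node states evolve as

    dx/dt = A x + B u        (continuous time)
    x[k+1] = A x[k] + B u[k] (discrete time)

where ``A[i, j]`` is the weight of the edge j -> i and ``B`` selects the
driver nodes: column k of B is the canonical basis vector of driver k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np


class TimeMode(str, Enum):
    """Whether the dynamics are a flow (continuous) or a map (discrete)."""

    CONTINUOUS = "continuous"
    DISCRETE = "discrete"


@dataclass(frozen=True)
class LinearNetwork:
    """A square state matrix together with a designated driver-node set.

    Parameters
    ----------
    A:
        Real ``(n, n)`` state (weighted adjacency) matrix with finite entries.
    drivers:
        Ordered, duplicate-free tuple of node indices in ``[0, n)`` that
        receive independent external inputs.
    time_mode:
        Continuous-time flow or discrete-time map.
    """

    A: np.ndarray
    drivers: tuple[int, ...]
    time_mode: TimeMode = TimeMode.CONTINUOUS
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        A = np.asarray(self.A, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError(f"state matrix must be square, got shape {A.shape}")
        if not np.all(np.isfinite(A)):
            raise ValueError("state matrix contains NaN or Inf entries")
        object.__setattr__(self, "A", A)
        drivers = tuple(int(d) for d in self.drivers)
        n = A.shape[0]
        if len(set(drivers)) != len(drivers):
            raise ValueError("driver indices must be distinct")
        if any(d < 0 or d >= n for d in drivers):
            raise ValueError(f"driver indices must lie in [0, {n})")
        object.__setattr__(self, "drivers", drivers)
        object.__setattr__(self, "time_mode", TimeMode(self.time_mode))

    @property
    def n(self) -> int:
        """Number of nodes."""
        return self.A.shape[0]

    @property
    def n_c(self) -> int:
        """Number of driver nodes."""
        return len(self.drivers)

    @property
    def B(self) -> np.ndarray:
        """Input matrix: ``B[i, k] = 1`` iff ``drivers[k] == i``."""
        B = np.zeros((self.n, self.n_c))
        for k, d in enumerate(self.drivers):
            B[d, k] = 1.0
        return B

    def with_drivers(self, drivers) -> "LinearNetwork":
        """Same matrix and time mode, different driver set."""
        return LinearNetwork(self.A, tuple(drivers), self.time_mode, dict(self.meta))


def all_drivers(A: np.ndarray, time_mode: TimeMode = TimeMode.CONTINUOUS,
                meta: dict | None = None) -> LinearNetwork:
    """Wrap a matrix as a network driven at every node (B = I)."""
    A = np.asarray(A, dtype=float)
    return LinearNetwork(A, tuple(range(A.shape[0])), time_mode, meta or {})
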