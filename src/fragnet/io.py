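"""Reading and writing networks and reports.

Supported matrix formats: MatrixMarket (``.mtx``, array or coordinate) and
a 3-column edge-list TSV.  The edge list stores ``source  target  weight``
with 1-based node indices and a ``# nodes=<n>`` header; following the
convention that ``A[i, j]`` is the influence of node j on node i, an edge
(source, target, w) sets ``A[target-1, source-1] = w``.  Missing edges are
exact zeros.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .network import LinearNetwork, TimeMode

__all__ = ["read_network", "write_network", "read_matrix", "write_matrix"]


class FormatError(ValueError):
    """Malformed network file."""


def _read_edgelist(path: Path) -> np.ndarray:
    n = None
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("nodes="):
                    n = int(stripped.split("=", 1)[1])
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected "
                                  f"'source target weight', got {line!r}")
            edges.append((int(parts[0]), int(parts[1]), float(parts[2])))
    if n is None:
        raise FormatError(f"{path}: missing '# nodes=<n>' header")
    A = np.zeros((n, n))
    seen = set()
    for src, dst, w in edges:
        if not (1 <= src <= n and 1 <= dst <= n):
            raise FormatError(f"{path}: edge ({src}, {dst}) outside 1..{n}")
        if (src, dst) in seen:
            raise FormatError(f"{path}: duplicate edge ({src}, {dst})")
        seen.add((src, dst))
        A[dst - 1, src - 1] = w
    return A


def _detect_format(path: Path) -> str:
    if path.suffix.lower() in {".mtx", ".mm"}:
        return "matrixmarket"
    return "edgelist_tsv"


def read_matrix(path, fmt: str | None = None) -> np.ndarray:
    """Read a dense square matrix from MatrixMarket or edge-list TSV."""
    path = Path(path)
    fmt = fmt or _detect_format(path)
    if fmt == "matrixmarket":
        M = scipy.io.mmread(path)
        if scipy.sparse.issparse(M):
            M = M.toarray()
        M = np.asarray(M, dtype=float)
    elif fmt == "edgelist_tsv":
        M = _read_edgelist(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise FormatError(f"{path}: declared matrix is not square "
                          f"(shape {M.shape})")
    return M


def read_network(path, fmt: str | None = None, drivers=None,
                 time_mode: TimeMode = TimeMode.CONTINUOUS) -> LinearNetwork:
    """Load a network file; ``drivers`` defaults to all nodes.

    Driver indices here are 0-based (library convention); the CLI converts
    from 1-based user input.
    """
    A = read_matrix(path, fmt)
    if drivers is None:
        drivers = range(A.shape[0])
    return LinearNetwork(A, tuple(drivers), time_mode)


def write_matrix(path, M: np.ndarray, fmt: str | None = None,
                 header: dict | None = None) -> None:
    """Write a dense matrix as MatrixMarket or edge-list TSV.

    Edge-list weights are written with ``repr`` precision, so a write/read
    round trip is bitwise exact.
    """
    path = Path(path)
    fmt = fmt or _detect_format(path)
    M = np.asarray(M, dtype=float)
    if fmt == "matrixmarket":
        comment = json.dumps(header) if header else ""
        scipy.io.mmwrite(path, M, comment=comment)
        return
    if fmt != "edgelist_tsv":
        raise ValueError(f"unknown format {fmt!r}")
    n = M.shape[0]
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write(f"# nodes={n}\n")
        for i in range(n):
            for j in range(n):
                if M[i, j] != 0.0:
                    # A[i, j] is the edge j -> i
                    fh.write(f"{j + 1}\t{i + 1}\t{float(M[i, j])!r}\n")


def write_network(path, net: LinearNetwork, fmt: str | None = None,
                  header: dict | None = None) -> None:
    hdr = dict(header or {})
    hdr.setdefault("drivers", ",".join(str(d + 1) for d in net.drivers))
    hdr.setdefault("time_mode", net.time_mode.value)
    write_matrix(path, net.A, fmt, hdr)
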