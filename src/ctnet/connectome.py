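"""Structural connectome container and plain-text matrix I/O.

The connectome is a weighted, symmetric, zero-diagonal matrix over cortical
regions (78 by default, mirroring the cortical parcels of the AAL atlas).
It routes long-range excitatory input: region j receives
``global_coupling * sum_k weights[j, k] * phi_e_k`` after row-normalization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = ["Connectome", "read_connectome", "write_connectome"]

_SYMMETRY_RTOL = 1e-8


@dataclass
class Connectome:
    """Weighted symmetric structural network plus a global coupling gain.

    Parameters
    ----------
    weights : ndarray, shape (n, n)
        Nonnegative symmetric matrix with zero diagonal; the graph of nonzero
        entries must be connected.
    labels : list of str, optional
        Region names; generated as ``R000..`` when omitted.
    global_coupling : float
        Scalar gain (V*s) applied to the row-normalized inter-regional
        excitatory input.
    inter_delay : float
        Inter-regional conduction delay (s); 0 by default.
    """

    weights: np.ndarray
    labels: list[str] | None = None
    global_coupling: float = 0.0
    inter_delay: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        scale = max(np.abs(w).max(), 1.0)
        if not np.allclose(w, w.T, rtol=0, atol=_SYMMETRY_RTOL * scale):
            raise ValueError("weights must be symmetric")
        w = 0.5 * (w + w.T)  # exact symmetry
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(np.diag(w) != 0):
            raise ValueError("weights must have zero diagonal")
        n = w.shape[0]
        if n >= 2:
            ncomp, _ = connected_components(w > 0, directed=False)
            if ncomp != 1:
                raise ValueError("graph of nonzero weights must be connected")
        if self.global_coupling < 0:
            raise ValueError("global_coupling must be >= 0")
        if self.inter_delay < 0:
            raise ValueError("inter_delay must be >= 0")
        if self.labels is None:
            self.labels = [f"R{i:03d}" for i in range(n)]
        elif len(self.labels) != n:
            raise ValueError("labels length must match matrix size")
        self.weights = w

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]

    def row_normalized(self) -> np.ndarray:
        """Weights scaled to unit row-sum (rows with no edges stay zero)."""
        s = self.weights.sum(axis=1, keepdims=True)
        s[s == 0] = 1.0
        return self.weights / s

    def replace(self, **kw) -> "Connectome":
        return dataclasses.replace(self, **kw)


def read_connectome(
    path: str | Path,
    global_coupling: float = 0.0,
    inter_delay: float = 0.0,
) -> Connectome:
    """Read a plain-text square weight matrix (tab- or comma-delimited).

    An optional first row of non-numeric labels is taken as region names.
    Near-symmetric input (relative tolerance 1e-8) is symmetrized by
    averaging; larger asymmetry is an error.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty connectome file")
    delim = "\t" if "\t" in lines[0] else ","
    first = lines[0].split(delim)
    labels = None
    try:
        [float(x) for x in first]
        data_lines = lines
    except ValueError:
        labels = [x.strip() for x in first]
        data_lines = lines[1:]
    w = np.array([[float(x) for x in ln.split(delim)] for ln in data_lines])
    return Connectome(
        weights=w,
        labels=labels,
        global_coupling=global_coupling,
        inter_delay=inter_delay,
    )


def write_connectome(
    conn: Connectome, path: str | Path, header: bool = True, delimiter: str = "\t"
) -> None:
    """Write the weight matrix as delimited text with an optional label row."""
    path = Path(path)
    with path.open("w") as fh:
        if header:
            fh.write(delimiter.join(conn.labels) + "\n")
        for row in conn.weights:
            fh.write(delimiter.join(repr(float(x)) for x in row) + "\n")
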