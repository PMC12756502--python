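"""Functional connectivity: Pearson matrices and Fisher-z edge vectors.

For a subject with ``n`` regions the connectivity matrix is the ``n x n``
Pearson correlation of the region time courses. All downstream statistics
operate on the strictly-upper-triangular edges, Fisher transformed
(z = atanh r) and enumerated in a single canonical order — (i < j),
row-major, 0-based — which every module in this package shares. For the
standard 116-region whole-brain parcellation this gives
116*115/2 = 6,670 edges.

Perfectly collinear region pairs (|r| = 1) are rejected rather than
clamped: the Fisher transform diverges there and a silent +-inf would
poison group means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cohort_io import ROITimeSeries
from .errors import (
    DegenerateSignalError,
    DomainError,
    InsufficientDataError,
    IntegrityError,
    ShapeError,
)

#: Maximum tolerated asymmetry |A - A.T| before a matrix is rejected.
SYMMETRY_TOL = 1e-10


def n_edges(n_regions: int) -> int:
    """Number of distinct node pairs, n*(n-1)/2."""
    return n_regions * (n_regions - 1) // 2


def edge_pairs(n_regions: int) -> np.ndarray:
    """The canonical edge enumeration as an (n_edges, 2) array of (i, j)
    with i < j, row-major, 0-based. Single source of truth for edge order."""
    iu = np.triu_indices(n_regions, k=1)
    return np.column_stack(iu)


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    subject_id: str = ""

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class EdgeVector:
    """Fisher-z connectivity values for the canonical upper-triangle edges."""

    z_values: np.ndarray
    n_regions: int
    subject_id: str = ""

    def __post_init__(self):
        expected = n_edges(self.n_regions)
        if self.z_values.shape != (expected,):
            raise ShapeError(
                f"edge vector for {self.n_regions} regions must have length "
                f"{expected}, got shape {self.z_values.shape}"
            )


def compute_fc_matrix(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson correlation of every region pair of one subject.

    Raises :class:`DegenerateSignalError` naming the first region with zero
    temporal variance, and :class:`InsufficientDataError` for fewer than 3
    time points.
    """
    data = np.asarray(ts.data, dtype=float)
    if data.shape[0] < 3:
        raise InsufficientDataError(
            f"need >=3 time points to correlate, got {data.shape[0]}"
        )
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise DegenerateSignalError(
            f"region {dead[0]} has zero temporal variance "
            f"({dead.size} degenerate region(s) total)"
        )
    c = np.corrcoef(data, rowvar=False)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    return ConnectivityMatrix(values=c, subject_id=ts.subject_id)


def fisher_z(r):
    """Fisher transform z = atanh(r) = 0.5*ln((1+r)/(1-r)).

    Accepts scalars or arrays; requires |r| < 1 everywhere.
    """
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise DomainError("Fisher transform requires |r| < 1")
    z = np.arctanh(r)
    return float(z) if z.ndim == 0 else z


def vectorize_upper(m: ConnectivityMatrix) -> EdgeVector:
    """Extract the canonical-order upper-triangle edges, Fisher transformed.

    Raises :class:`IntegrityError` if the matrix is asymmetric beyond
    ``SYMMETRY_TOL`` and :class:`DomainError` on any off-diagonal |r| >= 1.
    """
    a = np.asarray(m.values, dtype=float)
    if np.max(np.abs(a - a.T)) > SYMMETRY_TOL:
        raise IntegrityError(
            f"connectivity matrix for {m.subject_id!r} asymmetric beyond "
            f"{SYMMETRY_TOL:g}"
        )
    n = a.shape[0]
    r = a[np.triu_indices(n, k=1)]
    if np.any(np.abs(r) >= 1.0):
        raise DomainError(
            f"off-diagonal |r| >= 1 in matrix for {m.subject_id!r}; "
            "collinear regions cannot be Fisher transformed"
        )
    return EdgeVector(z_values=np.arctanh(r), n_regions=n, subject_id=m.subject_id)


def unvectorize(ev: EdgeVector) -> ConnectivityMatrix:
    """Rebuild the full correlation matrix (inverse of vectorize_upper)."""
    n = ev.n_regions
    a = np.eye(n)
    iu = np.triu_indices(n, k=1)
    r = np.tanh(ev.z_values)
    a[iu] = r
    a[(iu[1], iu[0])] = r
    return ConnectivityMatrix(values=a, subject_id=ev.subject_id)


def edge_vector_from_timeseries(ts: ROITimeSeries) -> EdgeVector:
    """Convenience: Pearson matrix then canonical Fisher-z edges."""
    return vectorize_upper(compute_fc_matrix(ts))


def compute_edge_vectors(
    timeseries: dict[str, ROITimeSeries],
) -> dict[str, EdgeVector]:
    """Edge vectors for a whole cohort, keyed by subject id."""
    return {
        sid: edge_vector_from_timeseries(ts) for sid, ts in timeseries.items()
    }


def save_edge_vector(ev: EdgeVector, path) -> None:
    """Delimited-text export with a header recording subject and size."""
    header = f"subject_id={ev.subject_id} n_regions={ev.n_regions}"
    np.savetxt(Path(path), ev.z_values, fmt="%.10g", header=header)


def load_edge_vector(path) -> EdgeVector:
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().lstrip("# ").strip()
    meta = dict(kv.split("=", 1) for kv in header.split())
    z = np.loadtxt(path)
    return EdgeVector(
        z_values=np.atleast_1d(z),
        n_regions=int(meta["n_regions"]),
        subject_id=meta.get("subject_id", ""),
    )


def save_fc_matrix(m: ConnectivityMatrix, path) -> None:
    header = f"subject_id={m.subject_id} n_regions={m.n_regions}"
    np.savetxt(Path(path), m.values, fmt="%.10g", header=header)
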