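"""Functional-connectivity edge features.

Parcel-level BOLD time series are summarised as the pairwise Pearson
correlation between all parcels ("edges"). Edge vectors use the strict upper
triangle of the correlation matrix in row-major order, are variance-stabilised
with the Fisher z transform (atanh), and multiple sessions are averaged
element-wise in z-space before being used as prediction features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: correlations of exactly +/-1 are clipped to 1 - CLIP before atanh
CLIP = 1e-7

RAW_R = "raw_r"
FISHER_Z = "fisher_z"


def edge_labels(n_parcels: int) -> list[tuple[int, int]]:
    """Ordered (i, j) parcel pairs, i < j, row-major upper triangle."""
    return [(i, j) for i in range(n_parcels) for j in range(i + 1, n_parcels)]


def n_edges(n_parcels: int) -> int:
    return n_parcels * (n_parcels - 1) // 2


@dataclass
class FeatureMatrix:
    """Participants x edges feature matrix.

    Parameters
    ----------
    values : ndarray of shape (n_participants, n_edges)
    edge_labels : ordered (i, j) parcel pairs, i < j, row-major
    row_labels : participant identifiers, aligned with rows
    space : ``"raw_r"`` (correlations in [-1, 1]) or ``"fisher_z"``
    """

    values: np.ndarray
    edge_labels: list[tuple[int, int]] = field(repr=False)
    row_labels: np.ndarray
    space: str = RAW_R

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_labels = np.asarray(self.row_labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (participants x edges)")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError("row_labels length does not match number of rows")
        if len(self.edge_labels) != self.values.shape[1]:
            raise ValueError("edge_labels length does not match number of columns")
        if self.space not in (RAW_R, FISHER_Z):
            raise ValueError(f"unknown space {self.space!r}")
        if self.space == RAW_R and self.values.size:
            amax = np.abs(self.values).max()
            if amax > 1 + 1e-12:
                raise ValueError(f"raw_r values must lie in [-1, 1]; max |r| = {amax}")

    @property
    def n_participants(self) -> int:
        return self.values.shape[0]

    def to_fisher_z(self) -> "FeatureMatrix":
        if self.space == FISHER_Z:
            return self
        return FeatureMatrix(fisher_z(self.values), self.edge_labels, self.row_labels, FISHER_Z)

    def select_rows(self, mask_or_idx) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values[mask_or_idx], self.edge_labels, self.row_labels[mask_or_idx], self.space
        )


def connectivity_edges(timeseries: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations over the strict upper triangle.

    Parameters
    ----------
    timeseries : ndarray of shape (n_parcels, n_timepoints)

    Returns
    -------
    ndarray of length p(p-1)/2, row-major upper-triangle order.
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be 2-D (parcels x timepoints)")
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant time series for parcel(s) {constant.tolist()}")
    r = np.corrcoef(ts)
    iu = np.triu_indices(ts.shape[0], k=1)
    return r[iu]


def devectorize(edges: np.ndarray, n_parcels: int) -> np.ndarray:
    """Rebuild the symmetric correlation matrix (unit diagonal) from an edge vector."""
    edges = np.asarray(edges, dtype=float)
    if edges.shape[-1] != n_edges(n_parcels):
        raise ValueError("edge vector length does not match n_parcels")
    mat = np.eye(n_parcels)
    iu = np.triu_indices(n_parcels, k=1)
    mat[iu] = edges
    mat[(iu[1], iu[0])] = edges
    return mat


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """Fisher z transform, z = atanh(r); |r| = 1 is clipped to 1 - 1e-7 first."""
    r = np.clip(np.asarray(r, dtype=float), -1 + CLIP, 1 - CLIP)
    out = np.arctanh(r)
    return out if out.ndim else float(out)


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return out if out.ndim else float(out)


def average_sessions(sessions: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Element-wise arithmetic mean of per-session edge vectors in z-space.

    All sessions must share edge labels, row labels and be in ``fisher_z``
    space already (averaging raw correlations is not the same operation).
    """
    if not sessions:
        raise ValueError("no sessions to average")
    first = sessions[0]
    for s in sessions[1:]:
        if s.edge_labels != first.edge_labels:
            raise ValueError("sessions have mismatched edge labels")
        if not np.array_equal(s.row_labels, first.row_labels):
            raise ValueError("sessions have mismatched participant labels")
    for s in sessions:
        if s.space != FISHER_Z:
            raise ValueError("average_sessions expects fisher_z space inputs")
    mean = np.mean([s.values for s in sessions], axis=0)
    return FeatureMatrix(mean, first.edge_labels, first.row_labels, FISHER_Z)


def read_timeseries_csv(path) -> np.ndarray:
    """Read one participant's time series (rows = timepoints, columns = parcels).

    Returns a parcels x timepoints array as expected by
    :func:`connectivity_edges`.
    """
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float).T
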