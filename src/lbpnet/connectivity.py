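"""Per-subject functional connectivity from parcel time series.

Functional connectivity (FC) between two parcels is the Pearson correlation
of their time series, Fisher-z transformed (z = atanh r) to make edge
weights approximately variance-stabilized. The diagonal is excluded: a
self-correlation of 1 maps to an infinite z and is never a usable edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["FCMatrix", "compute_fc", "mean_parcel_series"]

#: correlations are clipped to +/-(1 - _R_EPS) before atanh so that a
#: numerically perfect correlation yields a large finite z instead of inf
_R_EPS = 1e-12


@dataclass
class FCMatrix:
    """Symmetric Fisher-z connectivity matrix over N parcels.

    Attributes
    ----------
    values : ndarray of shape (N, N)
        Fisher-z transformed Pearson correlations. The diagonal is NaN and
        flagged as excluded; it must never be used as an edge weight.
    node_ids : ndarray of shape (N,)
        Ordered integer parcel identifiers.
    subject_id : str or None
        Owning subject, when known.
    """

    values: np.ndarray
    node_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.ndim != 2 or self.values.shape[1] != n:
            raise ValueError("FC matrix must be square")
        if self.node_ids is None:
            self.node_ids = np.arange(n)
        else:
            self.node_ids = np.asarray(self.node_ids)
            if self.node_ids.shape != (n,):
                raise ValueError("node_ids length must match matrix order")
        off = ~np.eye(n, dtype=bool)
        if not np.all(np.isfinite(self.values[off])):
            raise ValueError("off-diagonal FC values must be finite")
        if not np.allclose(self.values, self.values.T, atol=1e-10, equal_nan=True):
            raise ValueError("FC matrix must be symmetric")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]


def compute_fc(
    series: np.ndarray,
    node_ids: np.ndarray | None = None,
    subject_id: str | None = None,
) -> FCMatrix:
    """Compute the Fisher-z Pearson FC matrix of a nodes-by-time series.

    Parameters
    ----------
    series : ndarray of shape (n_nodes, n_timepoints)
        One row per parcel. Requires at least 3 timepoints and nonzero
        variance in every row.

    Returns
    -------
    FCMatrix
        Off-diagonal (i, j) holds atanh(r_ij) with r clipped away from +/-1;
        the diagonal is NaN (excluded).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D nodes-by-time array")
    n_nodes, n_t = series.shape
    if n_t < 3:
        raise ValueError(f"need >= 3 timepoints, got {n_t}")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains NaN or infinite values")
    sd = series.std(axis=1)
    # tolerance relative to magnitude: a literally constant row has sd at
    # floating-point noise level, not exactly 0
    scale = np.maximum(1.0, np.abs(series).max(axis=1))
    dead = np.flatnonzero(sd <= 1e-12 * scale)
    if dead.size:
        ids = np.arange(n_nodes) if node_ids is None else np.asarray(node_ids)
        raise ValueError(
            f"constant time series for node(s) {ids[dead].tolist()}: "
            "correlation undefined"
        )
    r = np.corrcoef(series)
    r = np.clip(r, -1.0 + _R_EPS, 1.0 - _R_EPS)
    r = (r + r.T) / 2.0  # enforce exact symmetry
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return FCMatrix(values=z, node_ids=node_ids, subject_id=subject_id)


def mean_parcel_series(
    voxel_series: np.ndarray, membership: np.ndarray
) -> np.ndarray:
    """Average member (voxel/vertex) rows into parcel time series.

    ``membership[m]`` is the parcel index of member row ``m``. Every parcel
    index in ``range(membership.max() + 1)`` must have at least one member.
    """
    voxel_series = np.asarray(voxel_series, dtype=float)
    membership = np.asarray(membership)
    if voxel_series.ndim != 2 or membership.shape != (voxel_series.shape[0],):
        raise ValueError("membership must assign one parcel per member row")
    n_nodes = int(membership.max()) + 1
    counts = np.bincount(membership, minlength=n_nodes)
    empty = np.flatnonzero(counts == 0)
    if empty.size:
        raise ValueError(f"parcel(s) {empty.tolist()} have no members")
    out = np.zeros((n_nodes, voxel_series.shape[1]))
    np.add.at(out, membership, voxel_series)
    return out / counts[:, None]
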