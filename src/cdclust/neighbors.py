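"""K-nearest-neighbor structure and 2D directional angles.

Everything downstream (direction centrality, adaptive parameter
estimation, noise scoring) consumes the :class:`NeighborGraph` built
here, so the neighbor search is exact and its tie rule is fixed:
equal distances are broken by ascending point index.  This makes every
later stage deterministic under permutation of the input rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import DegenerateNeighborhoodError, InputError, ParameterError

__all__ = [
    "PointSet",
    "NeighborGraph",
    "AngleSet",
    "build_knn",
    "central_angles_2d",
    "all_central_angles_2d",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class PointSet:
    """An n x d coordinate matrix with its distance-metric convention.

    Parameters
    ----------
    coords
        Real matrix of shape ``(n, d)``; rows are points.  Typically a
        low-dimensional embedding (2-5 D) of expression or feature data.
    metric
        Any metric name accepted by :func:`scipy.spatial.distance.cdist`.
        Default Euclidean.
    """

    coords: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise InputError("coords must be a 2-D matrix of shape (n, d)")
        if coords.shape[0] < 2 or coords.shape[1] < 2:
            raise InputError(
                f"need at least 2 points in at least 2 dimensions, "
                f"got shape {coords.shape}"
            )
        if not np.isfinite(coords).all():
            bad = np.argwhere(~np.isfinite(coords))[0]
            raise InputError(
                f"non-finite coordinate at row {bad[0]}, column {bad[1]}"
            )
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def d(self) -> int:
        return self.coords.shape[1]


@dataclass(frozen=True)
class NeighborGraph:
    """Exact KNN indices and distances, self excluded.

    ``indices`` and ``distances`` have shape ``(n, k)``; each row is
    sorted by distance, ties broken by ascending point index, and never
    contains the row's own index.
    """

    k: int
    indices: np.ndarray
    distances: np.ndarray


@dataclass(frozen=True)
class AngleSet:
    """Central angles around one center point, in radians.

    The k neighbor directions are sorted by azimuth (counterclockwise
    from the +x axis); ``angles`` are the successive differences with a
    single wrap-around term, so they always sum to 2*pi.
    """

    center: int
    angles: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return self.angles.shape[0]


def build_knn(points: PointSet, k: int) -> NeighborGraph:
    """Exact K-nearest-neighbor search under the point set's metric.

    Ties in distance are broken by ascending point index so the result
    is a pure function of the coordinates; permuting the input rows
    permutes the rows of the output accordingly.

    Raises
    ------
    ParameterError
        If ``k`` is not in ``[1, n-1]``.
    """
    k = int(k)
    n = points.n
    if not 1 <= k <= n - 1:
        raise ParameterError(f"k must satisfy 1 <= k <= n-1 = {n - 1}, got {k}")

    coords = points.coords
    indices = np.empty((n, k), dtype=np.intp)
    distances = np.empty((n, k), dtype=float)
    # Chunked brute force keeps the distance block at ~1e7 entries; a
    # stable argsort on distances yields the ascending-index tie rule
    # for free because columns are already in index order.
    chunk = max(1, int(1e7) // max(n, 1))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = cdist(coords[start:stop], coords, metric=points.metric)
        rows = np.arange(start, stop)
        block[rows - start, rows] = np.inf  # self-exclusion
        order = np.argsort(block, axis=1, kind="stable")[:, :k]
        indices[start:stop] = order
        distances[start:stop] = np.take_along_axis(block, order, axis=1)
    return NeighborGraph(k=k, indices=indices, distances=distances)


def _azimuths(vectors: np.ndarray) -> np.ndarray:
    """Angle of each (x, y) row, counterclockwise from +x, in [0, 2*pi)."""
    az = np.arctan2(vectors[..., 1], vectors[..., 0])
    return np.mod(az, TWO_PI)


def _angles_from_azimuths(az_sorted: np.ndarray) -> np.ndarray:
    """Successive differences of sorted azimuths with one wrap-around term."""
    out = np.empty_like(az_sorted)
    out[..., :-1] = np.diff(az_sorted, axis=-1)
    out[..., -1] = az_sorted[..., 0] + TWO_PI - az_sorted[..., -1]
    return out

def central_angles_2d(points: PointSet, graph: NeighborGraph, i: int) -> AngleSet:
    """Central angles formed by the KNNs of point ``i`` in 2D.

    Raises
    ------
    DegenerateNeighborhoodError
        If a neighbor coincides with the center (its direction is
        undefined).  The field-level DCM computation decides the
        fallback for such points.
    """
    if points.d != 2:
        raise ParameterError("central angles are defined for 2-D points only")
    vecs = points.coords[graph.indices[i]] - points.coords[i]
    if np.any(np.all(vecs == 0.0, axis=1)):
        raise DegenerateNeighborhoodError(
            f"a neighbor of point {i} coincides with it; direction undefined"
        )
    az = np.sort(_azimuths(vecs))
    return AngleSet(center=i, angles=_angles_from_azimuths(az))


def all_central_angles_2d(points: PointSet, graph: NeighborGraph) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized central angles for every point.

    Returns
    -------
    angles : (n, k) array
        Central angles per point (rows of degenerate centers are not
        meaningful — see ``degenerate``).
    degenerate : (n,) bool array
        True where at least one neighbor coincides with the center.
    """
    if points.d != 2:
        raise ParameterError("central angles are defined for 2-D points only")
    vecs = points.coords[graph.indices] - points.coords[:, None, :]
    degenerate = np.any(np.all(vecs == 0.0, axis=2), axis=1)
    az = np.sort(_azimuths(vecs), axis=1)
    return _angles_from_azimuths(az), degenerate
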