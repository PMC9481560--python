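"""Internal/boundary division and the cage-constrained connection rule.

Once every point carries a DCM score, clustering proceeds in four
steps:

1. *divide* — points with DCM >= T_DCM become boundary, the rest
   internal.  T_DCM can be given directly or derived from ``ratio``,
   the fraction of points to keep internal.
2. *reachable distances* — each internal point p_i gets
   r_i = min_j d(p_i, q_j) over all boundary points q_j.
3. *connect* — internal points i, j join the same cluster iff
   d(p_i, p_j) <= r_i + r_j (transitively).  Because r_i reaches no
   further than the nearest boundary point, the boundary points act as
   a cage: connections cannot jump across a boundary wall, so clusters
   of very different densities or weakly-connected pairs stay separate.
4. *assign* — each boundary point takes the label of its nearest
   internal point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

from .dcm import DCMField, compute_dcm_field
from .errors import AllBoundaryError, ParameterError
from .neighbors import PointSet, build_knn

__all__ = ["Partition", "divide", "reachable_distances", "connect_internal",
           "assign_boundary", "cdc_cluster"]


@dataclass(frozen=True)
class Partition:
    """Result of the full clustering procedure.

    ``is_boundary`` flags each point's role; ``reachable`` holds r_i for
    internal points (NaN for boundary); ``labels`` are contiguous
    cluster ids from 0; ``threshold_used`` is the T_DCM actually
    applied; ``m`` the number of internal points.
    """

    is_boundary: np.ndarray
    reachable: np.ndarray
    labels: np.ndarray
    threshold_used: float
    m: int

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1


def divide(
    dcm: DCMField,
    threshold: float | None = None,
    ratio: float | None = None,
) -> tuple[np.ndarray, float]:
    """Split points into internal and boundary by DCM.

    Exactly one of ``threshold`` / ``ratio`` must be given.  With
    ``ratio`` (the target fraction of internal points), T_DCM is the
    round(n * (1 - ratio))-th largest DCM — rank rounded half-up and
    clamped to [1, n-1] — so at least one point lands on each side.
    A point is boundary iff its DCM >= T_DCM (ties go to boundary,
    erring toward a stronger cage).

    Returns ``(is_boundary, threshold_used)``.
    """
    if (threshold is None) == (ratio is None):
        raise ParameterError("give exactly one of threshold= or ratio=")
    values = dcm.values
    n = values.shape[0]
    if ratio is not None:
        if not 0.0 <= ratio <= 1.0:
            raise ParameterError(f"ratio must be in [0, 1], got {ratio}")
        rank = int(np.floor(n * (1.0 - ratio) + 0.5))  # round half-up
        rank = min(max(rank, 1), n - 1)
        threshold = float(np.sort(values)[::-1][rank - 1])
    is_boundary = values >= threshold
    if is_boundary.all():
        raise AllBoundaryError(
            "every point classified as boundary; increase ratio or threshold"
        )
    if not is_boundary.any():
        warnings.warn(
            "no boundary points at this threshold; all points will join "
            "a single cluster",
            stacklevel=2,
        )
    return is_boundary, float(threshold)


def reachable_distances(points: PointSet, is_boundary: np.ndarray) -> np.ndarray:
    """Distance from each internal point to its nearest boundary point.

    Returns a length-n vector: r_i for internal points, NaN for
    boundary points.  With no boundary points at all, r_i = +inf (the
    rule's limit: every pair connects).
    """
    r = np.full(points.n, np.nan)
    internal = ~is_boundary
    if not is_boundary.any():
        r[internal] = np.inf
        return r
    d = cdist(
        points.coords[internal], points.coords[is_boundary], metric=points.metric
    )
    r[internal] = d.min(axis=1)
    return r


def connect_internal(
    points: PointSet, is_boundary: np.ndarray, reachable: np.ndarray
) -> np.ndarray:
    """Cluster the internal points under the reachable-distance rule.

    Two internal points join iff their distance is at most the sum of
    their reachable distances; clusters are the connected components of
    that relation.  Component ids are assigned by ascending smallest
    member index.  Exact O(m^2) pairwise evaluation.

    Returns a length-n vector with labels on internal points and -1 on
    boundary points.
    """
    labels = np.full(points.n, -1, dtype=int)
    internal_idx = np.flatnonzero(~is_boundary)
    m = internal_idx.shape[0]
    if m == 0:
        return labels
    r = reachable[internal_idx]
    if np.isinf(r).all():
        labels[internal_idx] = 0
        return labels
    d = cdist(points.coords[internal_idx], points.coords[internal_idx],
              metric=points.metric)
    adj = d <= r[:, None] + r[None, :]
    n_comp, comp = connected_components(csr_matrix(adj), directed=False)
    # relabel components in order of first appearance = smallest member
    order = {}
    for c in comp:
        if c not in order:
            order[c] = len(order)
    labels[internal_idx] = np.array([order[c] for c in comp])
    return labels


def assign_boundary(
    points: PointSet, is_boundary: np.ndarray, labels: np.ndarray
) -> np.ndarray:
    """Give each boundary point the label of its nearest internal point.

    Distance ties are broken toward the smallest internal-point index.
    """
    labels = labels.copy()
    boundary_idx = np.flatnonzero(is_boundary)
    internal_idx = np.flatnonzero(~is_boundary)
    if boundary_idx.size == 0 or internal_idx.size == 0:
        return labels
    d = cdist(points.coords[boundary_idx], points.coords[internal_idx],
              metric=points.metric)
    nearest = d.argmin(axis=1)  # argmin takes the first minimum: smallest index
    labels[boundary_idx] = labels[internal_idx[nearest]]
    return labels


def cdc_cluster(
    points: PointSet | np.ndarray,
    k: int,
    ratio: float | None = None,
    threshold: float | None = None,
    mode: str = "auto",
    dcm: DCMField | None = None,
) -> Partition:
    """Run the full boundary-seeking clustering procedure.

    Parameters
    ----------
    points
        Coordinates (or a :class:`PointSet`), typically a 2-5 D
        embedding.
    k
        Neighborhood size for the KNN search.
    ratio, threshold
        Exactly one of the internal-point fraction (default 0.9, inside
        the recommended 0.7-0.99 band) or a direct DCM threshold.
    mode
        DCM pathway: ``'auto'`` (angles in 2D, convex complex in d>=3),
        ``'2d'`` or ``'highd'``.
    dcm
        Precomputed DCM field (skips recomputation when sweeping
        thresholds).

    Deterministic for fixed input and parameters.
    """
    if threshold is None and ratio is None:
        ratio = 0.9
    if not isinstance(points, PointSet):
        points = PointSet(np.asarray(points, dtype=float))
    graph = build_knn(points, k)
    if dcm is None:
        dcm = compute_dcm_field(points, graph, mode=mode)
    is_boundary, threshold_used = divide(dcm, threshold=threshold, ratio=ratio)
    reachable = reachable_distances(points, is_boundary)
    labels = connect_internal(points, is_boundary, reachable)
    labels = assign_boundary(points, is_boundary, labels)
    return Partition(
        is_boundary=is_boundary,
        reachable=reachable,
        labels=labels,
        threshold_used=threshold_used,
        m=int((~is_boundary).sum()),
    )
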