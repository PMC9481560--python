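"""Adaptive choice of the two tunable parameters, k and T_DCM.

*k* is mildly sensitive and scales with the number of points n; an
empirical piecewise model gives a recommended range:

    k in [ceil(n/50), ceil(n/20)]              for 100 <= n <= 1000
    k in [ceil(log2 n + 10), 5 ceil(log2 n)]   for n >= 1000

(continuous at n = 1000, where both branches give [20, 50]).

*T_DCM* is sensitive, but it is pinned down once the number of boundary
points B is known: T_DCM is then the B-th largest DCM.  B is estimated
from a Delaunay triangulated irregular network (TIN) of the 2D points.
For one connected triangulation, every vertex degree sums to 2E, each
triangle has 3 edges, outer edges are the boundary polygon, and the 2D
Euler relation V + F - E = 1 closes the system to B = 2V - F - 2; for C
clusters (separate sub-networks) B = 2V - F - 2C, where F counts only
the intra-cluster triangles.  Cross-cluster triangles are detected with
a mutual-KNN rule: a triangle is cross-cluster when fewer than 3 of the
6 ordered vertex pairs (v_i, v_j) satisfy v_j in KNN(v_i).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.spatial import Delaunay

from .dcm import DCMField
from .errors import InputError, ParameterError
from .neighbors import NeighborGraph, PointSet

__all__ = ["KRange", "TINGraph", "ThresholdEstimate", "estimate_k",
           "build_tin", "flag_cross_triangles", "estimate_boundary_count",
           "estimate_tdcm"]


@dataclass(frozen=True)
class KRange:
    """Recommended neighborhood-size range for a given n."""

    k_low: int
    k_high: int

    @property
    def recommended(self) -> int:
        """Midpoint of the range, rounded up."""
        return math.ceil((self.k_low + self.k_high) / 2)


@dataclass(frozen=True)
class TINGraph:
    """Delaunay triangulated irregular network of a 2D point set."""

    n_vertices: int
    edges: np.ndarray       # (E, 2) sorted vertex pairs
    triangles: np.ndarray   # (F_total, 3) vertex triples
    cross_flags: np.ndarray | None = None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]


@dataclass(frozen=True)
class ThresholdEstimate:
    tdcm: float
    ratio: float
    boundary_count: int


def estimate_k(n: int) -> KRange:
    """Empirical k range as a function of the number of points.

    Raises
    ------
    ParameterError
        For n < 100, below the model's domain: pick k by hand there
        (a handful of neighbors is usually enough for tiny data).
    """
    n = int(n)
    if n < 100:
        raise ParameterError(
            f"the empirical k model is defined for n >= 100 (got {n}); "
            "for smaller data choose k manually, e.g. 3-10"
        )
    if n <= 1000:
        return KRange(math.ceil(n / 50), math.ceil(n / 20))
    return KRange(math.ceil(math.log2(n) + 10), 5 * math.ceil(math.log2(n)))


def build_tin(points: PointSet) -> TINGraph:
    """Delaunay triangulation of 2D points, with edge bookkeeping.

    Raises
    ------
    InputError
        For non-2D input or degenerate (e.g. collinear) configurations.
    """
    if points.d != 2:
        raise InputError("the TIN estimator is defined in 2D space only")
    if points.n < 3:
        raise InputError("need at least 3 points to triangulate")
    try:
        tri = Delaunay(points.coords)
    except Exception as exc:  # QhullError on collinear input
        raise InputError(f"triangulation failed: {exc}") from exc
    triangles = np.sort(tri.simplices, axis=1)
    if triangles.shape[0] == 0:
        raise InputError("degenerate (collinear) input: no triangles")
    edges = np.unique(
        np.sort(
            np.concatenate(
                [triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [0, 2]]]
            ),
            axis=1,
        ),
        axis=0,
    )
    return TINGraph(n_vertices=points.n, edges=edges, triangles=triangles)


def flag_cross_triangles(tin: TINGraph, graph: NeighborGraph) -> np.ndarray:
    """Flag triangles whose vertices are not mutually near.

    For each triangle, count over the 6 ordered vertex pairs how often
    one vertex lies in the other's KNN; fewer than 3 hits marks the
    triangle as cross-cluster.
    """
    n = tin.n_vertices
    rows = np.repeat(np.arange(n), graph.k)
    member = csr_matrix(
        (np.ones(n * graph.k, dtype=bool), (rows, graph.indices.ravel())),
        shape=(n, n),
    )
    t = tin.triangles
    score = np.zeros(t.shape[0], dtype=int)
    for a, b in ((0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)):
        score += np.asarray(member[t[:, a], t[:, b]]).ravel()
    return score < 3


def estimate_boundary_count(tin: TINGraph, n_clusters: int = 1) -> int:
    """Estimate the number of boundary points as B = 2V - F - 2C.

    F is the intra-cluster triangle count (cross-flagged triangles
    excluded when flags are present).  The estimate is clamped to
    [1, V] with a warning, since imperfect cross-triangle detection
    can push it out of range.  (B = V is legitimate for tiny
    triangulations where every vertex lies on the outer polygon.)
    """
    if n_clusters < 1:
        raise ParameterError("n_clusters must be >= 1")
    v = tin.n_vertices
    if tin.cross_flags is not None:
        f = int((~tin.cross_flags).sum())
    else:
        f = tin.n_triangles
    b = 2 * v - f - 2 * n_clusters
    if not 1 <= b <= v:
        warnings.warn(
            f"boundary-count estimate {b} outside [1, {v}]; clamping",
            stacklevel=2,
        )
        b = min(max(b, 1), v)
    return b


def estimate_tdcm(
    points: PointSet,
    graph: NeighborGraph,
    dcm: DCMField,
    n_clusters: int = 1,
) -> ThresholdEstimate:
    """TIN-based estimate of T_DCM (and the equivalent ratio).

    Builds the Delaunay TIN, removes cross-cluster triangles by the
    mutual-KNN rule, solves B = 2V - F - 2C, and returns the B-th
    largest DCM as the threshold.  ``n_clusters`` defaults to 1, the
    recommended fallback when the cluster count is unknown; the bias
    this introduces is only 2(C-1) points.

    Defined in 2D only (the Euler relation used is planar); for d > 2
    inputs it refuses rather than silently projecting.
    """
    if points.d != 2:
        raise ParameterError(
            "the TIN-based threshold estimator is defined for 2-D data only"
        )
    tin = build_tin(points)
    flags = flag_cross_triangles(tin, graph)
    tin = TINGraph(
        n_vertices=tin.n_vertices,
        edges=tin.edges,
        triangles=tin.triangles,
        cross_flags=flags,
    )
    b = min(estimate_boundary_count(tin, n_clusters), points.n - 1)
    tdcm = float(np.sort(dcm.values)[::-1][b - 1])
    return ThresholdEstimate(tdcm=tdcm, ratio=1.0 - b / points.n, boundary_count=b)
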