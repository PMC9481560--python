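"""The local Direction Centrality Metric (DCM).

A point deep inside a cluster sees its K nearest neighbors in every
direction; a point on a cluster boundary sees them in a limited
directional range.  The DCM quantifies this as the variance of the
directional coverage of the KNNs, normalized to [0, 1]:

* In 2D the KNN directions split the unit circle into k central angles
  ``a_1..a_k`` (summing to 2*pi) and

      DCM = k / (4 (k-1) pi^2) * sum_i (a_i - 2 pi / k)^2 .

  It is 0 iff all angles are equal (uniform coverage) and 1 iff one
  angle is 2*pi (all neighbors on one side).

* In d >= 3 the KNN directions are mapped onto the unit hypersphere and
  their convex hull — whose facets are (d-1)-simplices — subdivides the
  sphere into f curved units.  Each unit's volume is approximated by its
  facet's flat simplex volume plus an equal share of the global volume
  deficit, so the unit volumes sum exactly to the sphere's surface area
  S.  Then

      DCM = f / ((f-1) S^2) * sum_i (vol(u_i) - S/f)^2 .

  With exact arc lengths in 2D (f = k, S = 2*pi) this reduces to the
  angle formula.

Degenerate neighborhoods — fewer than d distinct directions after
deduplication, or directions spanning fewer than d dimensions — have
maximally one-sided coverage by construction and receive DCM = 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.special import gamma

from .errors import DegenerateNeighborhoodError, ParameterError
from .neighbors import (
    TWO_PI,
    AngleSet,
    NeighborGraph,
    PointSet,
    all_central_angles_2d,
)

__all__ = [
    "DCMField",
    "ConvexComplex",
    "dcm_2d",
    "map_to_unit_sphere",
    "build_convex_complex",
    "simplex_volume",
    "sphere_area",
    "allocate_unit_volumes",
    "normalized_volume_variance",
    "dcm_highd",
    "compute_dcm_field",
]


@dataclass(frozen=True)
class DCMField:
    """Per-point normalized DCM values, each in [0, 1]."""

    values: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ConvexComplex:
    """Convex hull of KNN directions on the unit hypersphere.

    ``simplices`` lists f facets, each a (d-1)-simplex given by d indices
    into ``directions``.  ``unit_volumes`` are the facet volumes after
    the global volume error ``S - sum(vol(s_i))`` has been split equally
    across facets, so they sum exactly to ``sphere_area``.
    """

    directions: np.ndarray
    simplices: np.ndarray
    simplex_volumes: np.ndarray
    sphere_area: float
    unit_volumes: np.ndarray | None = field(default=None)

    @property
    def f(self) -> int:
        return self.simplices.shape[0]

    @property
    def d(self) -> int:
        return self.directions.shape[1]


def dcm_2d(angles: AngleSet | np.ndarray) -> float:
    """Normalized 2D DCM from the k central angles.

    The raw angle variance ``1/k * sum (a_i - 2 pi/k)^2`` attains its
    maximum ``4 (k-1) pi^2 / k^2`` when one angle is 2*pi; dividing by
    that maximum yields a score in [0, 1].
    """
    a = angles.angles if isinstance(angles, AngleSet) else np.asarray(angles, float)
    k = a.shape[-1]
    if k < 2:
        raise ParameterError("DCM requires at least 2 central angles")
    dev = a - TWO_PI / k
    val = k / (4.0 * (k - 1) * np.pi**2) * np.sum(dev * dev, axis=-1)
    return float(np.clip(val, 0.0, 1.0)) if np.ndim(val) == 0 else np.clip(val, 0.0, 1.0)


def map_to_unit_sphere(points: PointSet, graph: NeighborGraph, i: int) -> np.ndarray:
    """Unit direction vectors from point ``i`` to its KNNs, deduplicated.

    Neighbors coinciding with the center are dropped (no direction), and
    exactly repeated directions are collapsed — repeated KNNs carry no
    extra directional information.

    Raises
    ------
    DegenerateNeighborhoodError
        If fewer than d distinct directions remain or they span fewer
        than d dimensions.
    """
    d = points.d
    vecs = points.coords[graph.indices[i]] - points.coords[i]
    norms = np.linalg.norm(vecs, axis=1)
    vecs = vecs[norms > 0.0]
    if vecs.shape[0] == 0:
        raise DegenerateNeighborhoodError(f"all KNNs of point {i} coincide with it")
    unit = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
    unit = np.unique(unit, axis=0)
    if unit.shape[0] < d:
        raise DegenerateNeighborhoodError(
            f"point {i}: only {unit.shape[0]} distinct KNN directions in {d}-D"
        )
    # The hull is full-dimensional only if the directions affinely span
    # d dimensions (at least d+1 points not contained in a hyperplane).
    if np.linalg.matrix_rank(unit[1:] - unit[0]) < d:
        raise DegenerateNeighborhoodError(
            f"point {i}: KNN directions span fewer than {d} dimensions"
        )
    return unit


def simplex_volume(vertices: np.ndarray) -> float:
    """Volume of the (d-1)-simplex spanned by d vertices in d-space.

    Computed as ``sqrt(det(A A^T)) / (d-1)!`` where the rows of A are
    the edge vectors from the last vertex: the Gram-determinant volume
    of the spanned parallelepiped divided by the simplex factor.
    Degenerate (affinely dependent) vertices give 0.
    """
    v = np.asarray(vertices, dtype=float)
    d = v.shape[0]
    if d < 2:
        raise ParameterError("a simplex facet needs at least 2 vertices")
    a = v[:-1] - v[-1]
    g = np.linalg.det(a @ a.T)
    return math.sqrt(max(g, 0.0)) / math.factorial(d - 1)


def sphere_area(d: int) -> float:
    """Surface area of the unit sphere in d dimensions: 2 pi^(d/2) / Gamma(d/2)."""
    return float(2.0 * np.pi ** (d / 2.0) / gamma(d / 2.0))


def build_convex_complex(directions: np.ndarray) -> ConvexComplex:
    """Convex hull of unit direction vectors, as a facet complex.

    Uses Qhull exactly (no joggle); on a precision failure the
    directions are retried once with a 1e-10 deterministic jitter, and a
    second failure is reported as a degenerate neighborhood.
    """
    directions = np.asarray(directions, dtype=float)
    d = directions.shape[1]
    try:
        hull = ConvexHull(directions)
    except QhullError:
        rng = np.random.default_rng(0)
        jittered = directions + rng.normal(scale=1e-10, size=directions.shape)
        try:
            hull = ConvexHull(jittered)
        except QhullError as exc:
            raise DegenerateNeighborhoodError(
                "convex hull of KNN directions is degenerate"
            ) from exc
    simplices = np.sort(hull.simplices, axis=1)
    simplices = simplices[np.lexsort(simplices.T[::-1])]  # canonical order
    vols = np.array([simplex_volume(directions[s]) for s in simplices])
    return ConvexComplex(
        directions=directions,
        simplices=simplices,
        simplex_volumes=vols,
        sphere_area=sphere_area(d),
    )


def allocate_unit_volumes(complex_: ConvexComplex) -> ConvexComplex:
    """Assign each subdivision unit its simplex volume plus an equal
    share of the global volume deficit, so units sum exactly to the
    sphere area while preserving the volume ordering of the simplices."""
    f = complex_.f
    s = complex_.sphere_area
    units = complex_.simplex_volumes + (s - complex_.simplex_volumes.sum()) / f
    return ConvexComplex(
        directions=complex_.directions,
        simplices=complex_.simplices,
        simplex_volumes=complex_.simplex_volumes,
        sphere_area=s,
        unit_volumes=units,
    )


def normalized_volume_variance(unit_volumes: np.ndarray, total: float) -> float:
    """Normalized variance of f subdivision-unit volumes summing to ``total``.

    ``f / ((f-1) total^2) * sum (v_i - total/f)^2`` — 0 when all units
    are equal, 1 when a single unit carries the whole total.
    """
    v = np.asarray(unit_volumes, dtype=float)
    f = v.shape[0]
    if f < 2:
        raise ParameterError("need at least 2 subdivision units")
    dev = v - total / f
    return float(np.clip(f / ((f - 1) * total * total) * np.sum(dev * dev), 0.0, 1.0))


def dcm_highd(complex_: ConvexComplex) -> float:
    """Normalized DCM of a convex complex (allocating unit volumes if needed)."""
    if complex_.unit_volumes is None:
        complex_ = allocate_unit_volumes(complex_)
    return normalized_volume_variance(complex_.unit_volumes, complex_.sphere_area)


def _dcm_field_2d(points: PointSet, graph: NeighborGraph) -> np.ndarray:
    angles, degenerate = all_central_angles_2d(points, graph)
    values = np.asarray(dcm_2d(angles), dtype=float)
    # Centers with coincident neighbors: recompute from the distinct
    # non-zero directions, or score 1 when fewer than two remain.
    for i in np.flatnonzero(degenerate):
        vecs = points.coords[graph.indices[i]] - points.coords[i]
        vecs = vecs[np.any(vecs != 0.0, axis=1)]
        if vecs.shape[0] < 2:
            values[i] = 1.0
        else:
            az = np.sort(np.mod(np.arctan2(vecs[:, 1], vecs[:, 0]), TWO_PI))
            a = np.empty_like(az)
            a[:-1] = np.diff(az)
            a[-1] = az[0] + TWO_PI - az[-1]
            values[i] = dcm_2d(a)
    return values


def _dcm_point_highd(points: PointSet, graph: NeighborGraph, i: int) -> float:
    try:
        directions = map_to_unit_sphere(points, graph, i)
        complex_ = allocate_unit_volumes(build_convex_complex(directions))
    except DegenerateNeighborhoodError:
        return 1.0
    return normalized_volume_variance(complex_.unit_volumes, complex_.sphere_area)


def compute_dcm_field(
    points: PointSet, graph: NeighborGraph, mode: str = "auto"
) -> DCMField:
    """Normalized DCM for every point.

    ``mode='auto'`` uses the angle formulation when d = 2 and the
    convex-complex formulation when d >= 3; ``'2d'`` and ``'highd'``
    force one pathway.  Degenerate neighborhoods receive DCM = 1 and
    will be classified as boundary downstream.
    """
    if mode not in ("auto", "2d", "highd"):
        raise ParameterError(f"unknown DCM mode {mode!r}")
    if mode == "2d" and points.d != 2:
        raise ParameterError("mode '2d' requires 2-D points")
    use_2d = points.d == 2 if mode == "auto" else mode == "2d"
    if use_2d:
        values = _dcm_field_2d(points, graph)
    else:
        values = np.array(
            [_dcm_point_highd(points, graph, i) for i in range(points.n)]
        )
    return DCMField(values=values)
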