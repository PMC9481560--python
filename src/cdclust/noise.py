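"""KNN-based noise elimination as a preprocessing step.

Scattered background points distort both the DCM field and the boundary
cage, so they are best removed before clustering.  Three scores, all
computed from the same KNN structure (and by default the same k) as the
clustering itself:

* **IDM** — inverse of the summed KNN distances; isolated points score
  low.
* **RKNN** — reverse-neighbor count, the number of points that list the
  given point among their KNNs; remote points score 0 and the scores
  always sum to n*k.
* **LOF** — the local outlier factor, the mean ratio of the local
  reachability density of a point's neighbors to its own; ~1 inside
  homogeneous regions, well above 1 for outliers.

Noise points are dropped before DCM computation and reported with label
-1 in outputs; they are never assigned to clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .neighbors import NeighborGraph, PointSet, build_knn

__all__ = ["NoiseScores", "idm_scores", "rknn_scores", "lof_scores", "denoise"]

_METHODS = ("idm", "rknn", "lof")


@dataclass(frozen=True)
class NoiseScores:
    """Per-point outlierness scores and the keep mask derived from them."""

    method: str
    scores: np.ndarray
    keep: np.ndarray

    @property
    def n_removed(self) -> int:
        return int((~self.keep).sum())


def idm_scores(points: PointSet, graph: NeighborGraph) -> np.ndarray:
    """Inverse of each point's summed KNN distances.

    A duplicate point (distance sum 0) scores +inf — maximally
    non-noise by definition.
    """
    sums = graph.distances.sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.where(sums > 0.0, 1.0 / np.where(sums > 0, sums, 1.0), np.inf)


def rknn_scores(points: PointSet, graph: NeighborGraph) -> np.ndarray:
    """Reverse-neighbor counts: how many points list i among their KNNs."""
    return np.bincount(graph.indices.ravel(), minlength=points.n).astype(float)


def lof_scores(points: PointSet, graph: NeighborGraph) -> np.ndarray:
    """Local outlier factor at the graph's k.

    reach_k(i <- j) = max(kdist(j), d(i, j)); the local reachability
    density is the inverse mean reach over a point's KNNs, and the LOF
    is the mean neighbor-to-self density ratio.
    """
    kdist = graph.distances[:, -1]
    reach = np.maximum(kdist[graph.indices], graph.distances)
    mean_reach = reach.mean(axis=1)
    with np.errstate(divide="ignore"):
        lrd = np.where(mean_reach > 0.0, 1.0 / np.where(mean_reach > 0, mean_reach, 1.0), np.inf)
    neighbor_lrd = lrd[graph.indices]
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = neighbor_lrd.mean(axis=1) / lrd
    return np.where(np.isfinite(ratio), ratio, 1.0)


def denoise(
    points: PointSet,
    method: str = "idm",
    cut: float = 0.1,
    k: int | None = None,
    graph: NeighborGraph | None = None,
    threshold: float | None = None,
) -> tuple[NoiseScores, PointSet]:
    """Score points and drop the most outlier-like fraction.

    Parameters
    ----------
    method
        ``'idm'``, ``'rknn'`` or ``'lof'``.
    cut
        Fraction of points to remove: the floor(cut * n) worst-scoring
        points (lowest idm/rknn, highest lof), ties broken by point
        index.  Ignored when ``threshold`` is given.
    k, graph
        Neighborhood: pass a prebuilt graph (shared-k with clustering)
        or a k to build one.
    threshold
        Absolute cutoff instead of a fraction: remove scores strictly
        below it (idm/rknn) or strictly above it (lof).

    Returns the scores (with keep mask) and the filtered point set.
    """
    if method not in _METHODS:
        raise ParameterError(f"unknown noise method {method!r}; use one of {_METHODS}")
    if graph is None:
        if k is None:
            raise ParameterError("denoise needs either graph= or k=")
        graph = build_knn(points, k)
    scorer = {"idm": idm_scores, "rknn": rknn_scores, "lof": lof_scores}[method]
    scores = scorer(points, graph)
    outlier_order = scores if method == "lof" else -scores  # high = worse
    keep = np.ones(points.n, dtype=bool)
    if threshold is not None:
        if method == "lof":
            keep = scores <= threshold
        else:
            keep = scores >= threshold
    else:
        if not 0.0 <= cut < 1.0:
            raise ParameterError(f"cut fraction must be in [0, 1), got {cut}")
        n_drop = int(np.floor(cut * points.n))
        if n_drop > 0:
            worst = np.lexsort((np.arange(points.n), -outlier_order))[:n_drop]
            keep[worst] = False
    if not keep.any():
        raise ParameterError("noise cutoff removed every point")
    filtered = PointSet(points.coords[keep], metric=points.metric)
    return NoiseScores(method=method, scores=scores, keep=keep), filtered
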