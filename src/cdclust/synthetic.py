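"""Seeded generators for the benchmark regimes that stress
density-based clustering.

Each generator emulates one of the classic failure modes: Gaussian
blobs of strongly heterogeneous size and density, nearly-touching
("weakly connected") cluster pairs, a ring enclosing an island blob,
elongated spindles, and uniform background noise.  Every generator is a
pure function of its parameters and an explicit seed — no global random
state — so datasets are reproducible bit-for-bit.

Ground-truth labels follow the generative component; injected noise is
labeled -1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Sequence

import numpy as np

from .errors import ParameterError

__all__ = ["SyntheticDataset", "gen_blobs", "gen_ring_island", "gen_spindles",
           "gen_noise_overlay"]


@dataclass(frozen=True)
class SyntheticDataset:
    """Coordinates, ground-truth labels (-1 = noise) and the recipe
    (generator name, parameters, seed) that reproduces them."""

    coords: np.ndarray
    labels: np.ndarray
    recipe: dict[str, Any]

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _split_counts(n: int, weights: Sequence[float]) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n among weights."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ParameterError("weights must be non-negative and not all zero")
    ideal = n * w / w.sum()
    counts = np.floor(ideal).astype(int)
    remainder = ideal - counts
    for i in np.argsort(-remainder)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def _truncated_normal(
    rng: np.random.Generator, n: int, d: int, sigma: float, trunc: float | None
) -> np.ndarray:
    """Isotropic Gaussian sample, optionally rejection-truncated to a
    ball of radius trunc * sigma (hard support edge)."""
    pts = rng.normal(scale=sigma, size=(n, d))
    if trunc is None:
        return pts
    limit = trunc * sigma
    bad = np.linalg.norm(pts, axis=1) > limit
    while bad.any():
        pts[bad] = rng.normal(scale=sigma, size=(int(bad.sum()), d))
        bad = np.linalg.norm(pts, axis=1) > limit
    return pts


def gen_blobs(
    n: int,
    centers: Sequence[Sequence[float]],
    sigmas: float | Sequence[float],
    weights: Sequence[float] | None = None,
    seed: int = 0,
    trunc: float | None = None,
) -> SyntheticDataset:
    """Gaussian mixture with per-component spread and share.

    Parameters
    ----------
    n
        Total number of points, apportioned among components by
        ``weights`` (equal shares by default) with deterministic
        largest-remainder rounding.
    centers
        Component centers, shape (c, d); d is taken from here.
    sigmas
        Isotropic standard deviation per component (scalar = shared).
    trunc
        Optional hard support radius in multiples of sigma (rejection
        sampling).  Used for the weakly-connected regime, where two
        clusters must nearly touch without overlapping.
    """
    centers = np.asarray(centers, dtype=float)
    c, d = centers.shape
    sig = np.broadcast_to(np.asarray(sigmas, dtype=float), (c,))
    counts = _split_counts(n, weights if weights is not None else np.ones(c))
    rng = np.random.default_rng(seed)
    coords, labels = [], []
    for j in range(c):
        coords.append(centers[j] + _truncated_normal(rng, counts[j], d, sig[j], trunc))
        labels.append(np.full(counts[j], j))
    return SyntheticDataset(
        coords=np.concatenate(coords),
        labels=np.concatenate(labels),
        recipe={
            "generator": "blobs", "n": n, "centers": centers.tolist(),
            "sigmas": sig.tolist(),
            "weights": list(weights) if weights is not None else None,
            "trunc": trunc, "seed": seed,
        },
    )


def gen_ring_island(
    n_ring: int,
    n_core: int,
    radius: float = 5.0,
    width: float = 0.3,
    core_sigma: float = 0.4,
    seed: int = 0,
) -> SyntheticDataset:
    """A ring cluster enclosing a central blob — an island distribution.

    Ring points have uniform angle and radius normal around ``radius``
    with scale ``width``, truncated at 3 widths so the annulus has a
    hard extent; the island is a Gaussian blob (truncated at 3 sigma)
    at the center.  Labels: ring = 0, island = 1.
    """
    if radius - 3 * width <= 3 * core_sigma:
        raise ParameterError(
            "ring inner radius must exceed the island extent "
            f"(radius - 3*width = {radius - 3 * width:.3g} <= "
            f"3*core_sigma = {3 * core_sigma:.3g})"
        )
    rng = np.random.default_rng(seed)
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n_ring)
    r = radius + _truncated_normal(rng, n_ring, 1, width, 3.0).ravel()
    ring = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    core = _truncated_normal(rng, n_core, 2, core_sigma, 3.0)
    return SyntheticDataset(
        coords=np.concatenate([ring, core]),
        labels=np.concatenate([np.zeros(n_ring, int), np.ones(n_core, int)]),
        recipe={
            "generator": "ring_island", "n_ring": n_ring, "n_core": n_core,
            "radius": radius, "width": width, "core_sigma": core_sigma,
            "seed": seed,
        },
    )


def gen_spindles(
    n_per: int | Sequence[int],
    centers: Sequence[Sequence[float]],
    lengths: float | Sequence[float] = 4.0,
    widths: float | Sequence[float] = 0.4,
    angles: float | Sequence[float] = 0.0,
    seed: int = 0,
) -> SyntheticDataset:
    """Elongated 2D clusters: rotated anisotropic Gaussians.

    ``lengths``/``widths`` are the major/minor standard deviations and
    ``angles`` the major-axis orientations in radians.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.shape[1] != 2:
        raise ParameterError("spindles are 2-D shapes")
    c = centers.shape[0]
    npc = np.broadcast_to(np.asarray(n_per, dtype=int), (c,))
    ln = np.broadcast_to(np.asarray(lengths, dtype=float), (c,))
    wd = np.broadcast_to(np.asarray(widths, dtype=float), (c,))
    ang = np.broadcast_to(np.asarray(angles, dtype=float), (c,))
    rng = np.random.default_rng(seed)
    coords, labels = [], []
    for j in range(c):
        local = rng.normal(size=(npc[j], 2)) * np.array([ln[j], wd[j]])
        ca, sa = np.cos(ang[j]), np.sin(ang[j])
        rot = np.array([[ca, -sa], [sa, ca]])
        coords.append(centers[j] + local @ rot.T)
        labels.append(np.full(npc[j], j))
    return SyntheticDataset(
        coords=np.concatenate(coords),
        labels=np.concatenate(labels),
        recipe={
            "generator": "spindles", "n_per": npc.tolist(),
            "centers": centers.tolist(), "lengths": ln.tolist(),
            "widths": wd.tolist(), "angles": ang.tolist(), "seed": seed,
        },
    )


def gen_noise_overlay(
    dataset: SyntheticDataset,
    n_noise: int,
    bbox: Sequence[Sequence[float]] | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Append uniform background noise (label -1) to a dataset.

    ``bbox`` is a (d, 2) array of per-dimension (low, high) bounds;
    default is the data's own bounding box.  The original coordinates
    are preserved exactly (append-only).
    """
    d = dataset.coords.shape[1]
    if bbox is None:
        bbox = np.column_stack([dataset.coords.min(axis=0), dataset.coords.max(axis=0)])
    bbox = np.asarray(bbox, dtype=float)
    if bbox.shape != (d, 2):
        raise ParameterError(f"bbox must have shape ({d}, 2)")
    rng = np.random.default_rng(seed)
    noise = rng.uniform(bbox[:, 0], bbox[:, 1], size=(n_noise, d))
    return SyntheticDataset(
        coords=np.concatenate([dataset.coords, noise]),
        labels=np.concatenate([dataset.labels, np.full(n_noise, -1)]),
        recipe={
            "generator": "noise_overlay", "base": dataset.recipe,
            "n_noise": n_noise, "bbox": bbox.tolist(), "seed": seed,
        },
    )
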