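# Methods

## Model and procedure

`cdclust` assumes clusters are regions of points whose interiors are
directionally surrounded by neighbors and whose outlines are traced by
points that see neighbors only within a limited angular range. The
procedure is:

1. **Exact KNN** under the configured metric (Euclidean by default).
   Ties in distance are broken by ascending point index, which makes
   the whole pipeline a pure function of the coordinates: permuting the
   input rows permutes the output identically. The search is a chunked
   brute-force distance sort rather than a space-partitioning tree; at
   the embedding sizes the method targets (thousands of points, 2–5
   dimensions) this is fast, and it keeps the tie rule bit-stable.
2. **DCM field.** In 2D, the k central angles between azimuth-sorted
   neighbor directions give DCM = k/(4(k−1)π²)·Σ(αᵢ − 2π/k)². In d ≥ 3
   the deduplicated neighbor directions on the unit hypersphere are
   hulled (Qhull, exact, no joggle); each facet is a (d−1)-simplex of
   volume √det(AAᵀ)/(d−1)! (rows of A are edge vectors from the last
   vertex), and each subdivision unit gets its simplex volume plus an
   equal share of S − Σvol(sᵢ), where S = 2π^{d/2}/Γ(d/2). The equal
   split keeps Σ units = S exactly and preserves the volume ordering of
   the facets, which is what the threshold step consumes. DCM is then
   f/((f−1)S²)·Σ(vol(uᵢ) − S/f)²; f is the facet count of the
   deduplicated hull, not k. With exact arc lengths in 2D this reduces
   algebraically to the angle formula (tested to 1e−9).
3. **Division.** Boundary iff DCM ≥ T_DCM (ties to boundary — a
   stronger cage). With `ratio` given instead, T_DCM is the
   round-half-up(n·(1−ratio))-th largest DCM, rank clamped to
   [1, n−1] so both sides are populated. Default ratio 0.9, inside the
   recommended 0.7–0.99 band.
4. **Connection.** rᵢ = distance to the nearest boundary point; two
   internal points join iff d ≤ rᵢ + rⱼ; clusters are the connected
   components (exact O(m²) evaluation through a sparse adjacency and
   `scipy.sparse.csgraph`). Component ids follow the smallest member
   index. Boundary points take their nearest internal point's label,
   distance ties toward the smaller index.

### Degenerate neighborhoods

A neighborhood whose directions collapse — fewer than d distinct
directions after deduplication, directions spanning fewer than d
dimensions (collinear/coplanar), or all neighbors coincident with the
center — has maximally one-sided coverage, so it receives DCM = 1 and
becomes boundary. This check runs *before* the hull call; without it, a
jittered hull of flat directions would produce two sliver facets of
nearly equal volume and a spuriously *low* DCM. On a genuine Qhull
precision failure the hull is retried once with a deterministic 1e−10
jitter, then the degenerate rule applies.

If every point ends up boundary the run aborts with advice to raise the
ratio; if none does (threshold above the maximum DCM), rᵢ = +∞ is the
rule's limit and all points join one cluster, with a warning. A known
failure mode is inherited from the model itself: if boundary detection
is incomplete, the cage can leak and nearby clusters merge. No
mitigation is attempted beyond the tie-to-boundary rule.

## Adaptive parameters

* **k from n** (domain n ≥ 100): ⌈n/50⌉–⌈n/20⌉ for n ≤ 1000,
  ⌈log₂n + 10⌉–5⌈log₂n⌉ above; both branches agree at n = 1000. The
  point estimate is the midpoint rounded up. Clustering quality is
  mildly sensitive to k, so the range, not the point, is the contract.
* **T_DCM from the Delaunay TIN** (2D only — the Euler relation used is
  planar; higher-dimensional input is refused rather than silently
  projected). Degree counting plus V + F − E = 1 give B = 2V − F − 2C
  boundary points over C cluster sub-networks, where F excludes
  cross-cluster triangles — those with fewer than 3 hits among the six
  ordered vertex pairs (vᵢ, vⱼ) with vⱼ ∈ KNN(vᵢ), at the same k as
  clustering. C defaults to 1 (its contribution, 2(C−1), is marginal).
  B is clamped to [1, V] — V is attainable for tiny triangulations
  where every vertex is on the outer polygon — and additionally capped
  at n − 1 when converted to a threshold, since thresholding needs an
  internal point. T_DCM is then the B-th largest DCM. The intermediate
  graph after triangle removal is never exposed as a clustering; the
  flagging rule is not reliable enough for that, only for counting.

## Noise elimination

Three scores over the shared NeighborGraph (same k as clustering by
default, overridable): IDM = 1/Σ distances (duplicates score +∞, kept
by definition), RKNN = reverse-neighbor count (sums to n·k exactly),
and LOF with the standard reachability-density definition (implemented
on the package's own graph so the tie rule and k are shared;
scikit-learn's implementation serves as an independent oracle in the
tests, agreeing to ~1e−10). The default cutoff policy is rank-based:
remove the ⌊cut·n⌋ worst-scoring points (an empirical quantile that is
deterministic under integer ties, which RKNN produces); an absolute
threshold is also available. Removed points are excluded before DCM
computation and reported with label −1, never assigned to clusters.

A structural note that shaped the test conditions: RKNN separates noise
only when noise points cannot fill their neighbor lists with fellow
noise — remote noise points otherwise reciprocate each other's links
and keep reverse counts near k. The noise benchmark therefore uses
k = 30, at least the injected-noise count.

## Synthetic generators

The generators emulate *regimes*, not any deposited benchmark files:
heterogeneous-density Gaussian mixtures (deterministic largest-remainder
apportionment of n among components, so density ratios are exact), a
ring-plus-island scene (ring radius truncated at ±3 widths, island at
±3σ, with a parameter check that the annulus clears the island),
rotated anisotropic spindles, and uniform background noise appended
over a bounding box. All randomness flows through one explicit seed.

`gen_blobs` takes an optional `trunc` (hard support radius in σ units,
rejection-sampled). Two uses: the weakly-connected regime — two blobs
with trunc = 1σ and a 2.5σ center gap nearly touch across a 0.5σ void,
which is the regime's intent; untruncated Gaussians at that gap overlap
~10 % of their mass, so no labeling could score ARI ≥ 0.95 against the
generative truth — and sharp-edged clusters for the noise benchmark,
where a bounded support keeps cluster density separated from background
density at the cutoff.

What the generators do *not* emulate: real embeddings' curved
manifolds, batch structure, and the distortions of the dimension
reduction itself. Passing recovery tests here shows the cage logic
works on the geometric regimes; it does not validate any particular
upstream embedding pipeline.

## Study sizes and numerical choices

Recovery tests use n = 600–1500 (2D) and n = 1000 (4D) — large enough
that the adaptive-k model applies and hull/TIN structure is stable,
small enough that the exact O(n²) paths stay interactive. Conservation
and consistency invariants are asserted at 1e−9; simplex volumes agree
with the independent Cayley–Menger determinant at 1e−9 across d = 2–5.
The DCM's analytic maximum is exact in exact arithmetic; in binary
floating point the input angle 2π carries an ulp-level error, so the
computed value can be 1 − O(1e−16), asserted at 1e−15.

## Evaluation metrics

ARI and NMI delegate to scikit-learn (NMI with arithmetic-mean
normalization — variants differ, so this is pinned); ACC solves the
cluster-to-truth assignment with `scipy.optimize.linear_sum_assignment`
on the contingency table; pairwise F1 comes from the pair-confusion
matrix. Predicted noise (−1) is excluded by default or scored as its
own cluster with `noise="own-cluster"`.

## Interfaces

The CLI (`cdc`) wraps the library 1:1: `cluster` (with `--auto` for
both adaptive parameters and `--denoise` for preprocessing),
`estimate`, `denoise`, `simulate`, `evaluate`. Input is the embedding
matrix itself; dimension reduction is deliberately left to the user's
preprocessing so that core results stay reproducible and
dependency-light. Coordinates are written at 17 significant digits and
parsed with a correctly-rounded parser, so file round trips are
bitwise exact.
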