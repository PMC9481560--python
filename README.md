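# cdclust — boundary-seeking clustering via direction centrality

`cdclust` clusters a numeric point matrix — typically a 2–5-dimensional
embedding of single-cell RNA-seq, CyTOF or other feature data — by first
finding the *boundary* points of clusters and then connecting the
*internal* points inside the cage the boundary forms. Because the split
into boundary and internal points depends only on the **directional**
distribution of each point's K nearest neighbors, not on local density,
the method handles two regimes that defeat density-based algorithms:
clusters of strongly heterogeneous density, and weakly-connected cluster
pairs joined by sparse bridges.

## The method

For a point with K nearest neighbors KNN(x), the **direction centrality
metric** (DCM) measures how unevenly the neighbors surround it. In 2D
the neighbor directions split the circle into k central angles
α₁…α_k (Σαᵢ = 2π) and

    DCM(x) = k / (4 (k−1) π²) · Σᵢ (αᵢ − 2π/k)²  ∈ [0, 1],

which is 0 iff the angles are all equal (the point is surrounded — an
internal point) and 1 iff a single angle is 2π (all neighbors to one
side — a boundary point). In d ≥ 3 dimensions the neighbor directions
are mapped onto the unit hypersphere; their convex hull subdivides the
sphere into f units whose volumes vᵢ (facet simplex volumes plus an
equal share of the global deficit, so Σvᵢ = S, the sphere's surface
area) generalize the angles:

    DCM(x) = f / ((f−1) S²) · Σᵢ (vᵢ − S/f)².

Points with DCM ≥ T_DCM become boundary points; T_DCM is usually set
through `ratio`, the fraction of points kept internal. Each internal
point pᵢ then gets a *reachable distance* rᵢ = min over boundary points
q of d(pᵢ, q), and two internal points join the same cluster iff
d(pᵢ, pⱼ) ≤ rᵢ + rⱼ. Since rᵢ never reaches past the nearest boundary
point, connections cannot cross a boundary wall. Boundary points finally
take the label of their nearest internal point.

Both parameters can be estimated from the data: k from an empirical
piecewise model in n, and T_DCM (2D only) from the Delaunay
triangulation via the planar Euler relation, which predicts the number
of boundary points as B = 2V − F − 2C. Three KNN-based noise filters
(inverse distance sum, reverse-neighbor count, local outlier factor)
are provided as an optional preprocessing step, and the usual external
metrics (ACC, NMI, ARI, pairwise F1) for evaluation.

## Worked example

```python
import numpy as np
from cdclust import gen_blobs, cdc_cluster, estimate_k, ari

# five blobs of very different size and density
ds = gen_blobs(
    1500,
    centers=[[0, 0], [12, 0], [0, 12], [12, 12], [6, 24]],
    sigmas=[0.5, 1.0, 0.7, 1.2, 0.4],
    weights=[0.4, 0.1, 0.25, 0.15, 0.1],
    seed=11,
)
k = estimate_k(ds.n).recommended
part = cdc_cluster(ds.coords, k=k, ratio=0.9)
print(k, part.n_clusters, part.m, round(part.threshold_used, 4),
      ari(ds.labels, part.labels))
```

prints

```
38 5 1350 0.1253 1.0
```

i.e. with the adaptive neighborhood size k = 38 and 90 % of points kept
internal (m = 1350, DCM threshold 0.1253), all five clusters are
recovered exactly (adjusted Rand index 1.0) despite the 9-fold density
differences.

The same pipeline from the shell:

```sh
cdc simulate blobs --n 1000 --clusters 3 --seed 1 --out data.csv --labels truth.csv
cdc cluster data.csv --k 20 --ratio 0.9 --out labels.csv
cdc evaluate truth.csv labels.csv
```

`cdc estimate data.csv` prints the adaptive k range and the TIN-based
T_DCM estimate; `cdc cluster … --auto` applies both. `--denoise
{idm,rknn,lof} --noise-cut 0.1` removes background noise first (those
rows get label −1 in the output).

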