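"""External cluster-agreement metrics: ACC, NMI, ARI, pairwise F1.

All four compare a predicted labeling against ground truth and are
invariant to renaming the labels on either side.  Predicted label -1
marks noise; by default those points are excluded from the comparison,
or they can be scored as a cluster of their own.

* ARI — Hubert-Arabie chance-adjusted Rand index, in [-1, 1].
* NMI — mutual information normalized by the arithmetic mean of the
  two label entropies, in [0, 1].
* ACC — fraction of points correctly labeled after the optimal
  one-to-one matching of predicted to true cluster ids (solved as a
  linear assignment problem).
* pairwise F1 — harmonic mean of precision and recall over point
  pairs placed in the same cluster.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix, pair_confusion_matrix

from .errors import InputError

__all__ = ["ari", "nmi", "acc", "f1_pairwise", "evaluate"]


def _prepare(truth, predicted, noise: str = "exclude"):
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape or truth.ndim != 1:
        raise InputError(
            f"label vectors must be 1-D and equal length, got shapes "
            f"{truth.shape} and {predicted.shape}"
        )
    if noise == "exclude":
        keep = predicted != -1
        truth, predicted = truth[keep], predicted[keep]
    elif noise != "own-cluster":
        raise InputError("noise policy must be 'exclude' or 'own-cluster'")
    if truth.size == 0:
        raise InputError("no non-noise points to score")
    return truth, predicted


def ari(truth, predicted, noise: str = "exclude") -> float:
    """Adjusted Rand index (Hubert-Arabie), chance-corrected to ~0."""
    t, p = _prepare(truth, predicted, noise)
    return float(adjusted_rand_score(t, p))


def nmi(truth, predicted, noise: str = "exclude") -> float:
    """Normalized mutual information (arithmetic-mean normalization)."""
    t, p = _prepare(truth, predicted, noise)
    return float(normalized_mutual_info_score(t, p, average_method="arithmetic"))


def acc(truth, predicted, noise: str = "exclude") -> float:
    """Clustering accuracy under optimal one-to-one cluster matching."""
    t, p = _prepare(truth, predicted, noise)
    c = contingency_matrix(t, p)
    rows, cols = linear_sum_assignment(-c)
    return float(c[rows, cols].sum() / t.size)


def f1_pairwise(truth, predicted, noise: str = "exclude") -> float:
    """F1 over co-clustered point pairs.

    Precision is the fraction of predicted same-cluster pairs that are
    truly co-clustered; recall the fraction of true pairs recovered.
    With no same-cluster pairs on either side (all singletons), the
    labelings agree vacuously and the score is 1.
    """
    t, p = _prepare(truth, predicted, noise)
    (tn, fp), (fn, tp) = pair_confusion_matrix(t, p)
    if tp + fp == 0 and tp + fn == 0:
        return 1.0
    if tp == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))


def evaluate(truth, predicted, noise: str = "exclude") -> dict[str, float]:
    """All four metrics as a dict (keys: acc, nmi, ari, f1)."""
    return {
        "acc": acc(truth, predicted, noise),
        "nmi": nmi(truth, predicted, noise),
        "ari": ari(truth, predicted, noise),
        "f1": f1_pairwise(truth, predicted, noise),
    }
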