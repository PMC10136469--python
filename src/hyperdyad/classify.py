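"""Group discrimination from IBS features.

Features are the band-averaged Fisher-z difference (block 2 - block 1)
at the channel pairs that showed a pre-correction-significant
group x block interaction.  A k-nearest-neighbour classifier with
leave-one-out cross-validation is scored at every odd k from 1 to 31;
the headline number is the accuracy averaged over k (KNN is noise-
sensitive in k, so no single k is trusted).  Significance comes from a
label-permutation null of the k-averaged accuracy.

Distances are Euclidean on features standardized with training-fold
statistics only (no leakage into the held-out dyad); distance ties are
broken toward the smaller dyad index, and with odd k and binary labels
vote ties cannot occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "ClassifyResult",
    "build_features",
    "knn_loo_accuracy",
    "k_averaged_accuracy",
    "label_permutation_p",
]


@dataclass
class FeatureTable:
    dyad_ids: list
    labels: np.ndarray          # 1 = couple, 0 = control
    features: np.ndarray        # (n_dyads, n_features)
    feature_pairs: list         # [(ch_m, ch_f)] column order


def build_features(scan, ibs, band) -> FeatureTable:
    """IBS-difference features (block2 - block1 band z) at the scan's
    pre-correction hit pairs, in the recorded pair order."""
    from .ibs import band_average
    if not scan.precorrection_hits:
        raise ValueError("empty hit list: run interaction_scan first and "
                         "check that any pair reaches the pre-correction alpha")
    bz = band_average(ibs, band)
    i1, i2 = ibs.seg_index("block1"), ibs.seg_index("block2")
    cols = [bz[:, ci - 1, cj - 1, i2] - bz[:, ci - 1, cj - 1, i1]
            for (ci, cj) in scan.precorrection_hits]
    feats = np.column_stack(cols)
    if not np.all(np.isfinite(feats)):
        raise ValueError("missing feature values (bad channels at a hit pair)")
    labels = np.array([1 if g == "couple" else 0 for g in ibs.groups])
    return FeatureTable(list(ibs.dyad_ids), labels, feats,
                        list(scan.precorrection_hits))


def _loo_neighbor_order(features: np.ndarray) -> np.ndarray:
    """For each held-out row i, the other rows sorted by Euclidean
    distance computed on features standardized with the training fold's
    (all-but-i) mean and sd.  Ties go to the smaller row index (stable
    sort on distance).  Returns (n, n-1) integer indices."""
    x = np.asarray(features, dtype=float)
    n = x.shape[0]
    order = np.empty((n, n - 1), dtype=int)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        mu = x[train].mean(axis=0)
        sd = x[train].std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        xt = (x[train] - mu) / sd
        xi = (x[i] - mu) / sd
        d = np.linalg.norm(xt - xi, axis=1)
        order[i] = train[np.argsort(d, kind="stable")]
    return order


def _accuracy_from_order(order: np.ndarray, labels: np.ndarray, ks) -> np.ndarray:
    """LOO accuracy per k given precomputed neighbour orders (majority
    vote of the k nearest training labels)."""
    n = order.shape[0]
    votes = np.cumsum(labels[order], axis=1)       # (n, n-1)
    ks = np.asarray(ks)
    pred = votes[:, ks - 1] * 2 > ks[None, :]      # True -> class 1
    return (pred == (labels[:, None] == 1)).mean(axis=0)


def knn_loo_accuracy(features, labels, k: int) -> float:
    """Leave-one-out accuracy of the k-NN majority vote."""
    labels = np.asarray(labels)
    n = len(labels)
    if not 1 <= k < n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_dyads={n}")
    order = _loo_neighbor_order(np.asarray(features, float))
    return float(_accuracy_from_order(order, labels, [k])[0])


@dataclass
class ClassifyResult:
    ks: tuple
    accuracy_per_k: np.ndarray
    mean_accuracy: float
    frac_k_above_chance: float      # fraction of k with accuracy > majority rate
    null_mean: float | None = None
    p: float | None = None
    n_null: int | None = None


def k_averaged_accuracy(features, labels, ks=tuple(range(1, 32, 2))) -> ClassifyResult:
    """Per-k LOO accuracies, their mean over the odd-k grid, and the
    fraction of k values individually above the majority-class rate."""
    labels = np.asarray(labels)
    n = len(labels)
    ks = tuple(ks)
    if any(k >= n or k < 1 for k in ks):
        raise ValueError("every k must satisfy 1 <= k < n_dyads")
    order = _loo_neighbor_order(np.asarray(features, float))
    acc = _accuracy_from_order(order, labels, ks)
    chance = max(np.mean(labels == 1), np.mean(labels == 0))
    return ClassifyResult(ks, acc, float(acc.mean()),
                          float(np.mean(acc > chance)))


def label_permutation_p(features, labels, n_iter: int = 10000, seed: int = 0,
                        ks=tuple(range(1, 32, 2))):
    """Label-permutation significance of the k-averaged LOO accuracy.

    Each iteration shuffles the group labels (class counts preserved)
    and recomputes the k-averaged accuracy; p uses the add-one
    convention (1 + #{null >= observed}) / (n_iter + 1).  Neighbour
    orders depend only on the features, so they are computed once.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    labels = np.asarray(labels)
    ks = tuple(ks)
    order = _loo_neighbor_order(np.asarray(features, float))
    observed = float(_accuracy_from_order(order, labels, ks).mean())
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    null = np.empty(n_iter)
    for it in range(n_iter):
        null[it] = _accuracy_from_order(order, rng.permutation(labels), ks).mean()
    p = (1 + int(np.sum(null >= observed))) / (n_iter + 1)
    result = k_averaged_accuracy(features, labels, ks)
    result.null_mean = float(null.mean())
    result.p = float(p)
    result.n_null = n_iter
    return result, null
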