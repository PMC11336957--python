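"""Evaluation metrics: kBET batch-mixing test, pair-counting clustering
agreement (RI/ARI/NMI), macro classification scores, and separability.

Standard quantities are delegated to scikit-learn / scipy; kBET is a
reimplementation of the test's core (per-cell chi-squared goodness of fit of
k-NN batch composition against global proportions), without the published
package's subsampling heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import cdist
from sklearn.metrics import (accuracy_score, adjusted_rand_score,
                             normalized_mutual_info_score,
                             precision_recall_fscore_support, rand_score)
from sklearn.neighbors import NearestNeighbors


@dataclass
class MetricReport:
    """One named metric value with the sample size and parameters used."""

    name: str
    value: float
    n_cells: int
    parameters: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"name": self.name, "value": self.value,
                "n_cells": self.n_cells, "parameters": self.parameters}


def kbet(embedding, batch_labels, k: int = 25, alpha: float = 0.05,
         seed: int = 0) -> MetricReport:
    """k-nearest-neighbour batch effect test rejection rate.

    For every cell, the batch composition of its k nearest neighbours
    (Euclidean; coordinate ties broken by a seeded jitter of ranks) is tested
    against the global batch proportions with a chi-squared goodness-of-fit
    test; the returned value is the fraction of cells rejected at `alpha`.
    Lower is better mixed; under perfect mixing the rate approaches alpha.
    """
    X = np.asarray(embedding, float)
    if X.ndim == 1:
        X = X[:, None]
    batches = np.asarray(batch_labels).astype(str)
    n = X.shape[0]
    uniq = np.unique(batches)
    if len(uniq) < 2:
        raise ValueError("kBET requires at least two batches")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    # deterministic tie-breaking among duplicated coordinates
    rng = np.random.default_rng(seed)
    Xj = X + rng.normal(scale=1e-9 * (1.0 + np.abs(X).max()), size=X.shape)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xj)
    _, idx = nn.kneighbors(Xj)
    neigh = idx[:, 1:]  # drop self
    global_props = np.array([(batches == b).mean() for b in uniq])
    expected = global_props * k
    rejected = 0
    code = {b: i for i, b in enumerate(uniq)}
    bcodes = np.vectorize(code.get)(batches)
    for i in range(n):
        counts = np.bincount(bcodes[neigh[i]], minlength=len(uniq))
        stat = ((counts - expected) ** 2 / expected).sum()
        p = stats.chi2.sf(stat, df=len(uniq) - 1)
        if p < alpha:
            rejected += 1
    return MetricReport(name="kbet_rejection_rate", value=rejected / n,
                        n_cells=n, parameters={"k": k, "alpha": alpha})


def clustering_metrics(truth, predicted) -> dict:
    """Rand index, adjusted Rand index and NMI (arithmetic-mean
    normalisation) between two partitions."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if len(truth) != len(predicted):
        raise ValueError("partitions must have equal length")
    if len(truth) < 2:
        raise ValueError("need at least two cells")
    return {
        "RI": float(rand_score(truth, predicted)),
        "ARI": float(adjusted_rand_score(truth, predicted)),
        "NMI": float(normalized_mutual_info_score(truth, predicted,
                                                  average_method="arithmetic")),
    }


def classification_metrics(truth, predicted, classes=None) -> dict:
    """Accuracy plus macro-averaged precision/recall/F1 (0/0 counted as 0)."""
    truth = np.asarray(truth).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if len(truth) != len(predicted):
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(truth))
    classes = [str(c) for c in classes]
    unseen = set(predicted) - set(classes)
    if unseen:
        raise ValueError(f"predicted labels outside the class set: {sorted(unseen)}")
    p, r, f1, _ = precision_recall_fscore_support(
        truth, predicted, labels=classes, average="macro", zero_division=0)
    return {"accuracy": float(accuracy_score(truth, predicted)),
            "macro_precision": float(p), "macro_recall": float(r),
            "macro_F1": float(f1)}


def separability(embedding, class_labels) -> float:
    """Mean silhouette coefficient (Euclidean) of the given classes in the
    embedding; higher means the classes are better discriminated.  This is a
    declared operationalisation of 'separability'.

    The intra-class mean distance a(i) averages over the full class including
    the cell itself (the population form), which makes the score exactly
    invariant to duplicating every cell with its label.
    """
    X = np.asarray(embedding, float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(class_labels).astype(str)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("separability requires at least two classes")
    if counts.min() < 2:
        singles = uniq[counts < 2].tolist()
        raise ValueError(f"classes with a single member: {singles}")
    D = cdist(X, X)
    masks = {c: labels == c for c in uniq}
    s = np.empty(len(labels))
    for i in range(len(labels)):
        a = D[i, masks[labels[i]]].mean()
        b = min(D[i, masks[c]].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())
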