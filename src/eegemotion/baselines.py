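"""Baseline classifiers for the internal comparison: Gaussian Naive Bayes,
an information-gain decision tree, and k-nearest neighbors.

All three are written from first principles with fully specified
tie-breaking so seeded runs are bit-reproducible; scikit-learn equivalents
serve only as independent cross-checks in the test suite.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .data_io import FeatureTable
from .preprocessing import ShapeError


class BaselineFitError(ValueError):
    pass


class BaselineConfigError(ValueError):
    pass


# --------------------------------------------------------------------------
# Naive Bayes

@dataclasses.dataclass
class NBModel:
    """Class priors plus per-class per-feature Gaussian parameters.

    Standard deviations are floored at 1e-9 + 1e-6 * (global feature sd) so
    a within-class constant feature never divides by zero.
    """

    priors: np.ndarray   # (C,), sums to 1
    means: np.ndarray    # (C, p)
    sds: np.ndarray      # (C, p), >= floor
    classes: np.ndarray  # class integers present in training data


def nb_fit(train: FeatureTable) -> NBModel:
    X, y = train.values, train.labels
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        raise BaselineFitError("every class needs at least 2 rows")
    priors = counts / counts.sum()
    floor = 1e-9 + 1e-6 * X.std(axis=0, ddof=1)
    means = np.stack([X[y == c].mean(axis=0) for c in classes])
    sds = np.stack([X[y == c].std(axis=0, ddof=1) for c in classes])
    sds = np.maximum(sds, floor)
    return NBModel(priors, means, sds, classes)


def nb_predict(model: NBModel, table: "FeatureTable | np.ndarray") -> np.ndarray:
    """argmax over classes of log prior + Σ_j log N(x_j; μ, σ).

    Log-domain throughout: with thousands of features the density product
    underflows double precision immediately.  Ties go to the lowest class.
    """
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    if X.shape[1] != model.means.shape[1]:
        raise ShapeError(f"expected {model.means.shape[1]} features, got {X.shape[1]}")
    # (n, C) log joint
    log_joint = np.log(model.priors)[None, :] + np.stack([
        (-0.5 * math.log(2 * math.pi) - np.log(model.sds[c])
         - 0.5 * ((X - model.means[c]) / model.sds[c]) ** 2).sum(axis=1)
        for c in range(len(model.classes))
    ], axis=1)
    return model.classes[np.argmax(log_joint, axis=1)]


# --------------------------------------------------------------------------
# Decision tree

@dataclasses.dataclass
class DTNode:
    feature: int = -1
    threshold: float = 0.0
    left: "DTNode | None" = None
    right: "DTNode | None" = None
    leaf_class: "int | None" = None


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _best_gain_split(X: np.ndarray, y: np.ndarray, n_classes: int,
                     min_samples_leaf: int) -> "tuple[int, float] | None":
    """Max information-gain (feature, midpoint threshold).

    Zero-gain splits of an impure node are accepted (standard CART
    behaviour: the XOR pattern has no positive-gain first split yet is
    perfectly separable two levels down); None only when no valid
    threshold exists.
    """
    n = len(y)
    parent_counts = np.bincount(y, minlength=n_classes).astype(float)
    parent_h = _entropy(parent_counts)
    best = None
    best_gain = -1.0
    for feat in range(X.shape[1]):
        vals = X[:, feat]
        order = np.argsort(vals, kind="stable")
        sv, sy = vals[order], y[order]
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), sy] = 1.0
        prefix = np.cumsum(onehot, axis=0)
        cut = np.flatnonzero(sv[:-1] < sv[1:])
        if min_samples_leaf > 1:
            cut = cut[(cut + 1 >= min_samples_leaf) & (n - cut - 1 >= min_samples_leaf)]
        if cut.size == 0:
            continue
        for i in cut:
            left = prefix[i]
            right = parent_counts - left
            nl, nr = left.sum(), right.sum()
            gain = parent_h - (nl * _entropy(left) + nr * _entropy(right)) / n
            if gain > best_gain + 1e-12:
                best_gain = gain
                best = (feat, 0.5 * (sv[i] + sv[i + 1]))
    return best


def dt_fit(train: FeatureTable, max_depth: "int | None" = None,
           min_samples_leaf: int = 1) -> DTNode:
    """Recursive binary tree; leaves take the most frequent label.

    Stops on purity, depth, leaf size, or when no split has positive gain.
    Leaf majority ties go to the lowest class index.
    """
    n_classes = int(train.labels.max()) + 1

    def build(X: np.ndarray, y: np.ndarray, depth: int) -> DTNode:
        counts = np.bincount(y, minlength=n_classes)
        majority = int(np.argmax(counts))
        depth_ok = max_depth is None or depth < max_depth
        if np.count_nonzero(counts) <= 1 or not depth_ok \
                or len(y) < 2 * min_samples_leaf:
            return DTNode(leaf_class=majority)
        split = _best_gain_split(X, y, n_classes, min_samples_leaf)
        if split is None:
            return DTNode(leaf_class=majority)
        feat, thr = split
        mask = X[:, feat] <= thr
        return DTNode(feature=feat, threshold=thr,
                      left=build(X[mask], y[mask], depth + 1),
                      right=build(X[~mask], y[~mask], depth + 1))

    return build(train.values, train.labels, 0)


def dt_predict(tree: DTNode, table: "FeatureTable | np.ndarray") -> np.ndarray:
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    out = np.empty(X.shape[0], dtype=int)
    for i, row in enumerate(X):
        node = tree
        while node.leaf_class is None:
            node = node.left if row[node.feature] <= node.threshold else node.right
        out[i] = node.leaf_class
    return out


# --------------------------------------------------------------------------
# K-nearest neighbors

@dataclasses.dataclass(frozen=True)
class KNNConfig:
    k: int = 5
    distance: str = "euclidean"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise BaselineConfigError("k must be positive")
        if self.distance != "euclidean":
            raise BaselineConfigError(f"unsupported distance {self.distance!r}")


def knn_predict(train: FeatureTable, test: "FeatureTable | np.ndarray",
                config: KNNConfig = KNNConfig()) -> np.ndarray:
    """Majority vote among the k nearest training rows per test row.

    Distance ties break by training-row index (stable sort); vote ties by
    lowest class index.
    """
    Xte = test.values if isinstance(test, FeatureTable) else np.asarray(test, dtype=float)
    Xtr, ytr = train.values, train.labels
    if config.k > len(ytr):
        raise BaselineConfigError(f"k={config.k} exceeds n_train={len(ytr)}")
    if Xte.shape[1] != Xtr.shape[1]:
        raise ShapeError("train/test feature widths differ")
    n_classes = int(ytr.max()) + 1
    out = np.empty(Xte.shape[0], dtype=int)
    for i, row in enumerate(Xte):
        d2 = ((Xtr - row) ** 2).sum(axis=1)
        nearest = np.argsort(d2, kind="stable")[:config.k]
        votes = np.bincount(ytr[nearest], minlength=n_classes)
        out[i] = int(np.argmax(votes))
    return out
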