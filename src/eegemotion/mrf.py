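"""Modified Random Forest with a margin-based node-split score.

Each randomized tree splits on the (feature, threshold) pair maximizing the
weighted-child average of the node margin score

    elf(R) = Σ_k f_k · (f_k − 1/C) = Σ_k f_k² − 1/C,

where f_k are the node's (weight-weighted) class frequencies and C the
number of classes: the score is 0 for a uniform node and 1 − 1/C for a
pure one, so maximizing it rewards class distributions far above the
uniform rate.  Algebraically it is the negated Gini impurity shifted by a
constant, which makes its greedy optimum well defined.

Between forest-growing rounds, per-instance weights are recomputed in
proportion to each row's out-of-bag cross-entropy loss −log p(true class),
normalized to sum to n, and the forest is regrown with those weights
entering the split criterion and the leaf class frequencies — rows the
current forest handles badly count for more when placing splits and
casting leaf votes.  Bootstrap sampling stays uniform: reweighting the
sampler itself starves the trees of the easy majority of the data and
demonstrably degrades out-of-bag loss, whereas criterion-level weighting
leaves coverage intact.  An optional deterministic-annealing refinement
pseudo-labels unlabeled rows from the temperature-sharpened predictive
distribution and refits, with the temperature decreasing over rounds.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .data_io import FeatureTable
from .preprocessing import ShapeError

_PROB_FLOOR = 1e-12


class FitError(ValueError):
    pass


class SearchError(ValueError):
    pass


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class MRFConfig:
    """Forest hyperparameters.

    features_per_split defaults to ceil(sqrt(p)) when None.
    n_margin_classes overrides the C in the node score's 1/C term (an
    expert knob; the additive constant does not change which split wins).
    weighting_rounds counts the loss-driven reweight-and-regrow passes
    after the initial uniform-weight forest.
    """

    n_trees: int = 100
    features_per_split: "int | None" = None
    max_depth: "int | None" = None
    min_samples_leaf: int = 1
    weighting_rounds: int = 1
    n_margin_classes: "int | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_leaf < 1:
            raise ConfigError("n_trees and min_samples_leaf must be positive")
        if self.weighting_rounds < 0:
            raise ConfigError("weighting_rounds must be nonnegative")


def node_margin_score(freqs: np.ndarray, n_classes: "int | None" = None) -> float:
    """Σ_k f_k·(f_k − 1/C) for a class-frequency vector summing to 1."""
    freqs = np.asarray(freqs, dtype=float)
    if abs(freqs.sum() - 1.0) > 1e-9 or np.any(freqs < 0):
        raise ValueError("frequencies must be nonnegative and sum to 1")
    c = n_classes if n_classes is not None else len(freqs)
    return float(np.dot(freqs, freqs) - 1.0 / c)


def empirical_loss(predicted: np.ndarray, true_class: int) -> float:
    """Cross-entropy −log p(true class), probability floored at 1e-12."""
    predicted = np.asarray(predicted, dtype=float)
    if abs(predicted.sum() - 1.0) > 1e-6:
        raise ValueError("predicted distribution must sum to 1")
    return -math.log(max(float(predicted[true_class]), _PROB_FLOOR))


@dataclasses.dataclass
class Split:
    feature: int
    threshold: float
    score: float   # weighted-child average margin score


def _weighted_counts(y: np.ndarray, w: np.ndarray, n_classes: int) -> np.ndarray:
    counts = np.zeros(n_classes)
    np.add.at(counts, y, w)
    return counts


def _margin_of_counts(counts: np.ndarray, inv_c: float) -> float:
    total = counts.sum()
    if total <= 0:
        return 0.0
    return float(np.dot(counts, counts)) / (total * total) - inv_c


def best_split(X: np.ndarray, y: np.ndarray, w: np.ndarray,
               candidate_features: np.ndarray, n_classes: int,
               min_samples_leaf: int = 1,
               inv_c: "float | None" = None) -> "Split | None":
    """Exact search over midpoint thresholds of every candidate feature.

    Returns the split maximizing the weight-weighted average of the two
    children's margin scores, or None when nothing improves the parent.
    Ties break to the lowest feature index, then the lowest threshold.
    """
    candidate_features = np.asarray(candidate_features, dtype=int)
    if candidate_features.size == 0:
        raise SearchError("empty candidate feature set")
    n = len(y)
    if inv_c is None:
        inv_c = 1.0 / n_classes
    parent_counts = _weighted_counts(y, w, n_classes)
    parent_score = _margin_of_counts(parent_counts, inv_c)
    total_w = w.sum()

    best: "Split | None" = None
    for feat in np.sort(candidate_features):
        vals = X[:, feat]
        order = np.argsort(vals, kind="stable")
        sv, sy, sw = vals[order], y[order], w[order]
        # prefix weighted class counts after each row
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), sy] = sw
        prefix = np.cumsum(onehot, axis=0)
        cut = np.flatnonzero(sv[:-1] < sv[1:])          # split after position i
        if min_samples_leaf > 1:
            cut = cut[(cut + 1 >= min_samples_leaf) & (n - cut - 1 >= min_samples_leaf)]
        if cut.size == 0:
            continue
        left = prefix[cut]
        right = parent_counts[None, :] - left
        wl = left.sum(axis=1)
        wr = total_w - wl
        sl = np.where(wl > 0, (left * left).sum(axis=1) / np.maximum(wl, 1e-300) ** 2 - inv_c, 0.0)
        sr = np.where(wr > 0, (right * right).sum(axis=1) / np.maximum(wr, 1e-300) ** 2 - inv_c, 0.0)
        child = (wl * sl + wr * sr) / total_w
        k = int(np.argmax(child))                        # first max → lowest threshold
        if child[k] > parent_score + 1e-12 and (best is None or child[k] > best.score + 1e-12):
            thr = 0.5 * (sv[cut[k]] + sv[cut[k] + 1])
            best = Split(int(feat), float(thr), float(child[k]))
    return best


@dataclasses.dataclass
class _TreeNode:
    feature: int = -1
    threshold: float = 0.0
    left: "int" = -1
    right: "int" = -1
    freqs: "np.ndarray | None" = None   # leaf class-frequency vector


class Tree:
    """Axis-aligned binary tree; leaves hold class-frequency vectors."""

    def __init__(self) -> None:
        self.nodes: list[_TreeNode] = []

    def grow(self, X: np.ndarray, y: np.ndarray, w: np.ndarray,
             n_classes: int, config: MRFConfig, rng: np.random.Generator,
             inv_c: float) -> None:
        s = config.features_per_split or math.ceil(math.sqrt(X.shape[1]))
        s = min(s, X.shape[1])

        def build(idx: np.ndarray, depth: int) -> int:
            node = _TreeNode()
            self.nodes.append(node)
            me = len(self.nodes) - 1
            counts = _weighted_counts(y[idx], w[idx], n_classes)
            depth_ok = config.max_depth is None or depth < config.max_depth
            split = None
            if depth_ok and len(idx) >= 2 * config.min_samples_leaf \
                    and np.count_nonzero(counts) > 1:
                feats = rng.choice(X.shape[1], size=s, replace=False)
                split = best_split(X[idx], y[idx], w[idx], feats, n_classes,
                                   config.min_samples_leaf, inv_c)
            if split is None:
                node.freqs = counts / counts.sum()
                return me
            node.feature, node.threshold = split.feature, split.threshold
            mask = X[idx, split.feature] <= split.threshold
            node.left = build(idx[mask], depth + 1)
            node.right = build(idx[~mask], depth + 1)
            return me

        build(np.arange(len(y)), 0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        n_classes = next(nd.freqs.shape[0] for nd in self.nodes if nd.freqs is not None)
        out = np.empty((X.shape[0], n_classes))
        for i, row in enumerate(X):
            j = 0
            while self.nodes[j].freqs is None:
                nd = self.nodes[j]
                j = nd.left if row[nd.feature] <= nd.threshold else nd.right
            out[i] = self.nodes[j].freqs
        return out


@dataclasses.dataclass
class Forest:
    trees: list[Tree]
    bootstrap_indices: list[np.ndarray]
    instance_weights: np.ndarray    # positive, sums to n_train
    config: MRFConfig
    n_classes: int
    n_features: int


def _grow_round(X: np.ndarray, y: np.ndarray, weights: np.ndarray,
                config: MRFConfig, n_classes: int, inv_c: float,
                rng: np.random.Generator) -> tuple[list[Tree], list[np.ndarray]]:
    n = len(y)
    trees, boots = [], []
    for _ in range(config.n_trees):
        idx = rng.choice(n, size=n, replace=True)
        tree = Tree()
        tree.grow(X[idx], y[idx], weights[idx], n_classes, config, rng, inv_c)
        trees.append(tree)
        boots.append(idx)
    return trees, boots


def _oob_losses(X: np.ndarray, y: np.ndarray, trees: list[Tree],
                boots: list[np.ndarray], n_classes: int) -> np.ndarray:
    """Per-row −log p(true) from trees whose bootstrap missed the row.

    Rows that every tree saw get the uniform-distribution loss log C.
    """
    n = len(y)
    prob_sum = np.zeros((n, n_classes))
    votes = np.zeros(n)
    for tree, idx in zip(trees, boots):
        in_bag = np.zeros(n, dtype=bool)
        in_bag[idx] = True
        oob = ~in_bag
        if oob.any():
            prob_sum[oob] += tree.predict_proba(X[oob])
            votes[oob] += 1
    losses = np.full(n, math.log(n_classes))
    seen = votes > 0
    p_true = prob_sum[seen, y[seen]] / votes[seen]
    losses[seen] = -np.log(np.maximum(p_true, _PROB_FLOOR))
    return losses


def fit_forest(train: FeatureTable, config: MRFConfig = MRFConfig()) -> Forest:
    """Grow the forest, then run the loss-driven reweighting rounds.

    Round 0 uses unit instance weights; each weighting round sets the
    weights proportional to the out-of-bag cross-entropy of the previous
    forest (normalized to sum n) and regrows all trees with the weights
    applied inside the margin-score split search and the leaf frequencies.
    """
    X, y = train.values, train.labels
    classes = np.unique(y)
    if classes.size < 2:
        raise FitError("training data must contain at least 2 classes")
    n_classes = int(y.max()) + 1
    inv_c = 1.0 / (config.n_margin_classes or n_classes)
    rng = np.random.default_rng(config.seed)
    n = len(y)

    weights = np.ones(n)
    trees, boots = _grow_round(X, y, weights, config, n_classes, inv_c, rng)
    for _ in range(config.weighting_rounds):
        losses = _oob_losses(X, y, trees, boots, n_classes)
        weights = losses + 1e-6                  # keep strictly positive
        weights = weights * (n / weights.sum())
        trees, boots = _grow_round(X, y, weights, config, n_classes, inv_c, rng)
    return Forest(trees, boots, weights, config, n_classes, X.shape[1])


def predict_proba(forest: Forest, X: np.ndarray) -> np.ndarray:
    """Average of leaf class-frequency vectors across trees."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != forest.n_features:
        raise ShapeError(f"expected {forest.n_features} features, got {X.shape[1]}")
    probs = np.zeros((X.shape[0], forest.n_classes))
    for tree in forest.trees:
        probs += tree.predict_proba(X)
    return probs / len(forest.trees)


def predict(forest: Forest, table: "FeatureTable | np.ndarray") -> tuple[np.ndarray, np.ndarray]:
    """(labels, per-row probability vectors); vote ties → lowest class index."""
    X = table.values if isinstance(table, FeatureTable) else np.asarray(table, dtype=float)
    probs = predict_proba(forest, X)
    return np.argmax(probs, axis=1), probs


def mean_oob_loss(forest: Forest, train: FeatureTable) -> float:
    """Mean out-of-bag cross-entropy of the fitted forest on its training set."""
    losses = _oob_losses(train.values, train.labels, forest.trees,
                         forest.bootstrap_indices, forest.n_classes)
    return float(losses.mean())


def geometric_schedule(start: float = 0.5, ratio: float = 0.5,
                       rounds: int = 3) -> list[float]:
    """Default annealing temperatures: start·ratio^k, k = 0..rounds-1.

    Starting below τ=1 matters: at τ=1 pseudo-labels are sampled from the
    raw predictive distribution, which injects the forest's full error
    rate as label noise; τ=0.5 squares the probabilities first.
    """
    if start <= 0 or not 0 < ratio < 1 or rounds < 1:
        raise ConfigError("need start > 0, 0 < ratio < 1, rounds >= 1")
    return [start * ratio ** k for k in range(rounds)]


def ssl_refine(forest: Forest, labeled: FeatureTable, unlabeled: np.ndarray,
               schedule: "list[float] | None" = None) -> Forest:
    """Deterministic-annealing semi-supervised refinement.

    Per temperature τ (strictly decreasing, positive): sample pseudo-labels
    for the unlabeled rows from the forest's predictive distribution
    sharpened as p^{1/τ} (renormalized; τ below 1e-8 means hard argmax),
    refit on labeled + pseudo-labeled rows, continue with the new forest.
    """
    unlabeled = np.asarray(unlabeled, dtype=float)
    if schedule is None:
        schedule = geometric_schedule()
    if len(schedule) == 0 or any(t <= 0 for t in schedule):
        raise ConfigError("schedule must be nonempty positive temperatures")
    if any(b >= a for a, b in zip(schedule, schedule[1:])):
        raise ConfigError("temperature schedule must be strictly decreasing")
    if unlabeled.shape[0] == 0:
        return fit_forest(labeled, forest.config)

    rng = np.random.default_rng(forest.config.seed + 1)
    current = forest
    for tau in schedule:
        probs = predict_proba(current, unlabeled)
        if tau < 1e-8:
            pseudo = np.argmax(probs, axis=1)
        else:
            sharp = np.maximum(probs, _PROB_FLOOR) ** (1.0 / tau)
            sharp /= sharp.sum(axis=1, keepdims=True)
            cum = np.cumsum(sharp, axis=1)
            u = rng.random(len(sharp))
            pseudo = (u[:, None] > cum).sum(axis=1)
        X = np.vstack([labeled.values, unlabeled])
        y = np.concatenate([labeled.labels, pseudo])
        merged = FeatureTable(X, list(labeled.feature_names), y)
        current = fit_forest(merged, forest.config)
    return current
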