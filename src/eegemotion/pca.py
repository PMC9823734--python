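"""Principal component analysis via the correlation matrix, from scratch.

The recipe: standardize each column to zero mean and unit sample standard
deviation (n-1 denominator), form the correlation matrix K = GᵀG/(n-1),
eigendecompose it, express each eigenvalue's contribution to total variance
β_i = γ_i / Σγ and the cumulative contribution CC_i = Σ_{j≤i} β_j, and
retain the smallest m with CC_m ≥ threshold (default 0.85, the usual
"cumulative contribution at least 85%" rule).  A comprehensive-evaluation
score — the eigenvalue-weighted mean of the retained component scores — is
exposed as well; it is a per-segment summary index, not a pipeline stage.

Fitting happens on training data only; new data is standardized with the
training means and standard deviations before projection.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_io import FeatureTable
from .preprocessing import ShapeError


class DegenerateColumnError(ValueError):
    """A column with zero sample standard deviation cannot be standardized."""


@dataclasses.dataclass
class PCAModel:
    """Fitted PCA state.

    eigenvalues are nonincreasing and sum to p (trace of a correlation
    matrix); eigenvectors are orthonormal columns; contributions sum to 1;
    m is the smallest index (1-based count) with cumulative contribution
    >= threshold.
    """

    means: np.ndarray          # training column means, length p
    sds: np.ndarray            # training column sample sds, length p
    eigenvalues: np.ndarray    # length p, sorted descending
    eigenvectors: np.ndarray   # (p, p), column i pairs with eigenvalues[i]
    contributions: np.ndarray  # β, length p
    cumulative: np.ndarray     # CC, length p, nondecreasing
    m: int
    threshold: float
    feature_names: list[str]      # columns the model was fit on (post-drop)
    n_input_features: int = 0     # width of the original input table
    kept_indices: "np.ndarray | None" = None   # original-column positions

    def __post_init__(self) -> None:
        if self.n_input_features == 0:
            self.n_input_features = len(self.means)
        if self.kept_indices is None:
            self.kept_indices = np.arange(len(self.means))


def standardize(table: FeatureTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-standardize: G_ij = (a_ij - mean_j) / sd_j, sample sd (n-1).

    Raises DegenerateColumnError naming the first zero-variance column.
    """
    if table.n < 2:
        raise ValueError("standardization needs at least 2 rows")
    means = table.values.mean(axis=0)
    sds = table.values.std(axis=0, ddof=1)
    zero = np.flatnonzero(sds == 0)
    if zero.size:
        raise DegenerateColumnError(
            f"column {table.feature_names[zero[0]]!r} has zero variance")
    return (table.values - means) / sds, means, sds


def correlation_matrix(G: np.ndarray) -> np.ndarray:
    """K = GᵀG/(n-1) for a standardized matrix G."""
    n = G.shape[0]
    return (G.T @ G) / (n - 1)


def contribution_selection(eigenvalues: np.ndarray, threshold: float
                           ) -> tuple[np.ndarray, np.ndarray, int]:
    """(β, CC, m) from a sorted eigenvalue list.

    β_i = γ_i / Σγ, CC_i the running sum, m the smallest count with
    CC_m ≥ threshold (all p components when the threshold is unreachable).
    """
    eigenvalues = np.asarray(eigenvalues, dtype=float)
    contributions = eigenvalues / eigenvalues.sum()
    cumulative = np.cumsum(contributions)
    reached = cumulative >= threshold - 1e-12
    m = int(np.argmax(reached) + 1) if reached.any() else len(cumulative)
    return contributions, cumulative, m


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    # Reproducible sign convention: largest-magnitude loading positive.
    idx = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[idx, np.arange(vectors.shape[1])])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit(table: FeatureTable, threshold: float = 0.85,
        drop_constant: bool = False) -> PCAModel:
    """Fit the full recipe on a training table.

    drop_constant removes zero-variance columns instead of raising.
    """
    names = list(table.feature_names)
    work = table
    keep = np.arange(table.p)
    if drop_constant:
        sds = table.values.std(axis=0, ddof=1)
        keep = np.flatnonzero(sds > 0)
        if keep.size == 0:
            raise DegenerateColumnError("all columns have zero variance")
        names = [names[j] for j in keep]
        work = table.with_values(table.values[:, keep], names)

    G, means, sds = standardize(work)
    K = correlation_matrix(G)
    eigenvalues, eigenvectors = np.linalg.eigh(K)
    # eigh returns ascending order; stable descending sort keeps tie order.
    order = np.argsort(-eigenvalues, kind="stable")
    eigenvalues = np.clip(eigenvalues[order], 0.0, None)
    eigenvectors = _fix_signs(eigenvectors[:, order])

    contributions, cumulative, m = contribution_selection(eigenvalues, threshold)
    return PCAModel(means, sds, eigenvalues, eigenvectors,
                    contributions, cumulative, m, threshold, names,
                    n_input_features=table.p, kept_indices=keep)


def transform(model: PCAModel, table: FeatureTable) -> FeatureTable:
    """Project onto the m retained components; labels carried through."""
    if table.p == model.n_input_features:
        values = table.values[:, model.kept_indices]
    elif table.p == len(model.means):
        values = table.values
    else:
        raise ShapeError(f"table has {table.p} features, model expects "
                         f"{model.n_input_features}")
    G = (values - model.means) / model.sds
    scores = G @ model.eigenvectors[:, :model.m]
    names = [f"pc_{i + 1}" for i in range(model.m)]
    return table.with_values(scores, names)


def comprehensive_score(model: PCAModel, scores: np.ndarray) -> np.ndarray:
    """Eigenvalue-weighted mean of retained component scores, per row."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    gamma = model.eigenvalues[:model.m]
    if scores.shape[1] != model.m:
        raise ShapeError(f"expected {model.m} component columns, got {scores.shape[1]}")
    return scores @ gamma / gamma.sum()
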