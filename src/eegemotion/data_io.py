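"""Feature-table I/O and the seeded stratified train/test split.

The pipeline consumes tabular EEG data: one row per recording segment,
numeric statistical-feature columns (the kind a consumer headband such as
the Muse, electrodes TP9/AF7/AF8/TP10, exports after on-device windowed
feature extraction) plus a categorical emotion label column with values
negative / neutral / positive.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

#: Fixed label encoding used everywhere in the package.
CLASS_NAMES: tuple[str, ...] = ("negative", "neutral", "positive")
CLASS_TO_INT: dict[str, int] = {c: i for i, c in enumerate(CLASS_NAMES)}


class FormatError(ValueError):
    """CSV layout problem (missing label column, ...)."""


class ParseError(ValueError):
    """A feature cell could not be parsed as a number."""


class LabelError(ValueError):
    """A label value outside {negative, neutral, positive}."""


class SplitError(ValueError):
    """Stratified split preconditions violated."""


@dataclasses.dataclass
class FeatureTable:
    """Numeric segments-by-features matrix with per-row emotion labels.

    Parameters
    ----------
    values : (n, p) float array
        Unitless statistical features, all finite.
    feature_names : list of str, length p, unique.
    labels : (n,) int array
        Encoded labels: negative=0, neutral=1, positive=2.
    """

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise FormatError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 1 or p < 1:
            raise FormatError("need at least one row and one feature")
        if not np.all(np.isfinite(self.values)):
            raise ParseError("feature values must all be finite")
        if len(self.feature_names) != p:
            raise FormatError(f"{len(self.feature_names)} names for {p} features")
        if len(set(self.feature_names)) != p:
            raise FormatError("feature names must be unique")
        if self.labels.shape != (n,):
            raise FormatError("labels length must equal the row count")
        if self.labels.min() < 0 or self.labels.max() >= len(CLASS_NAMES):
            raise LabelError("labels must be encoded in 0..2")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def label_names(self) -> list[str]:
        return [CLASS_NAMES[i] for i in self.labels]

    def select(self, idx: np.ndarray) -> "FeatureTable":
        """Row subset as a new table."""
        idx = np.asarray(idx, dtype=int)
        return FeatureTable(self.values[idx], list(self.feature_names), self.labels[idx])

    def with_values(self, values: np.ndarray, feature_names: list[str]) -> "FeatureTable":
        """Same rows/labels, different feature matrix (e.g. after extraction)."""
        return FeatureTable(values, feature_names, self.labels.copy())


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default 80:20, stratified, seeded)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")


def encode_labels(raw: "pd.Series | list[str]") -> np.ndarray:
    """Map label strings case-insensitively onto the fixed integer order."""
    out = np.empty(len(raw), dtype=int)
    for i, value in enumerate(raw):
        key = str(value).strip().lower()
        if key not in CLASS_TO_INT:
            raise LabelError(
                f"unknown label {value!r} at row {i}; expected one of {CLASS_NAMES}"
            )
        out[i] = CLASS_TO_INT[key]
    return out


def read_feature_table(path: "str | Path", label_column: str = "label") -> FeatureTable:
    """Read a CSV feature table in the headband-export layout.

    All non-label columns must be numeric; the label column holds
    negative/neutral/positive (any case).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if label_column not in df.columns:
        raise FormatError(f"label column {label_column!r} not found in {path.name}")
    labels = encode_labels(df[label_column])
    feature_names = [c for c in df.columns if c != label_column]
    if not feature_names:
        raise FormatError("no feature columns besides the label column")
    values = np.empty((len(df), len(feature_names)), dtype=float)
    for j, name in enumerate(feature_names):
        col = df[name]
        for i, cell in enumerate(col):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {cell!r} at row {i}, column {name!r}"
                ) from None
    return FeatureTable(values, feature_names, labels)


def write_feature_table(table: FeatureTable, path: "str | Path",
                        label_column: str = "label") -> None:
    """Write a table in the same CSV dialect `read_feature_table` accepts.

    Uses repr-precision floats so a round trip reproduces values exactly.
    """
    df = pd.DataFrame(table.values, columns=table.feature_names)
    df[label_column] = [name.upper() for name in table.label_names()]
    df.to_csv(path, index=False, float_format="%.17g")


def stratified_split(table: FeatureTable, spec: SplitSpec) -> tuple[FeatureTable, FeatureTable]:
    """Seeded stratified 80:20 (by default) partition into train and test.

    Per-class test counts are allocated by the largest-remainder method so
    the total test size equals round(n * (1 - train_fraction)) while class
    proportions are preserved up to rounding.  Same seed, same split.
    """
    train_idx, test_idx = split_indices(table.labels, spec)
    return table.select(train_idx), table.select(test_idx)


def split_indices(labels: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Index-level split used by :func:`stratified_split`."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    rng = np.random.default_rng(spec.seed)
    test_fraction = 1.0 - spec.train_fraction

    if not spec.stratified:
        perm = rng.permutation(n)
        n_test = int(round(n * test_fraction))
        return np.sort(perm[n_test:]), np.sort(perm[:n_test])

    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        bad = CLASS_NAMES[classes[np.argmin(counts)]]
        raise SplitError(f"class {bad!r} has fewer than 2 members")

    # Largest-remainder allocation of the per-class test quota.
    target_total = int(round(n * test_fraction))
    quotas = counts * test_fraction
    base = np.floor(quotas).astype(int)
    remainder = target_total - base.sum()
    order = np.argsort(-(quotas - base), kind="stable")
    for k in order[:remainder]:
        base[k] += 1

    train_parts, test_parts = [], []
    for cls, n_test_c in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        perm = rng.permutation(len(members))
        test_parts.append(members[perm[:n_test_c]])
        train_parts.append(members[perm[n_test_c:]])
    train_idx = np.sort(np.concatenate(train_parts))
    test_idx = np.sort(np.concatenate(test_parts))
    return train_idx, test_idx
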