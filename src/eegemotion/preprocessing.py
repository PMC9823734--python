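"""Min-max feature scaling, fit on training data only.

Each feature is mapped to (x - min) / (max - min) with the training-set
column minima and maxima.  Constant training columns map to 0.  Test values
outside the training range are NOT clipped, so test data may land outside
[0, 1]; clipping would discard the information that a segment is out of the
training envelope.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from .data_io import FeatureTable


class ShapeError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ScalerParams:
    minimum: np.ndarray   # per-feature training minimum, length p
    maximum: np.ndarray   # per-feature training maximum, length p

    def __post_init__(self) -> None:
        object.__setattr__(self, "minimum", np.asarray(self.minimum, dtype=float))
        object.__setattr__(self, "maximum", np.asarray(self.maximum, dtype=float))
        if self.minimum.shape != self.maximum.shape or self.minimum.ndim != 1:
            raise ShapeError("min/max must be equal-length vectors")
        if np.any(self.maximum < self.minimum):
            raise ValueError("maximum must be >= minimum elementwise")

    def to_json(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(
            {"minimum": self.minimum.tolist(), "maximum": self.maximum.tolist()}))

    @classmethod
    def from_json(cls, path: "str | Path") -> "ScalerParams":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["minimum"]), np.array(d["maximum"]))


def scale_fit(train: FeatureTable) -> ScalerParams:
    """Columnwise training min and max."""
    return ScalerParams(train.values.min(axis=0), train.values.max(axis=0))


def scale_apply(table: FeatureTable, params: ScalerParams) -> FeatureTable:
    """Map each value to (x - min)/(max - min); constant features map to 0."""
    if table.p != len(params.minimum):
        raise ShapeError(f"table has {table.p} features, scaler expects {len(params.minimum)}")
    span = params.maximum - params.minimum
    safe = np.where(span > 0, span, 1.0)
    scaled = (table.values - params.minimum) / safe
    scaled[:, span == 0] = 0.0
    return table.with_values(scaled, list(table.feature_names))
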