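"""End-to-end pipeline: split → scale → extract → PCA → classify → evaluate.

Every stochastic stage draws its seed from one root seed via named
substreams, so a run is fully determined by (input table, config).  The
extractor and PCA stages can each be skipped to ablate them, in which case
the classifier consumes the scaled (or extracted) features directly.
"""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from . import baselines, dna_rcnn, metrics, mrf, pca
from .data_io import FeatureTable, SplitSpec, stratified_split
from .preprocessing import scale_apply, scale_fit

_STAGE_SEEDS = {"split": 11, "extractor": 23, "classifier": 37}


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage that caused it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    seed: int = 0
    train_fraction: float = 0.8
    use_extractor: bool = True
    use_pca: bool = True
    pca_threshold: float = 0.85
    classifier: str = "mrf"          # mrf | nb | dt | knn
    network: "dna_rcnn.NetworkConfig | None" = None
    forest: "mrf.MRFConfig | None" = None
    knn_k: int = 5


@dataclasses.dataclass
class PipelineResult:
    report: metrics.MetricsReport
    cm: metrics.ConfusionMatrix
    predictions: np.ndarray
    test_labels: np.ndarray
    n_components: "int | None"
    effective: dict[str, Any]


def _substream(root: int, stage: str) -> int:
    return (root * 1_000_003 + _STAGE_SEEDS[stage]) % (2 ** 31)


def _fit_predict(train: FeatureTable, test: FeatureTable,
                 config: PipelineConfig) -> np.ndarray:
    seed = _substream(config.seed, "classifier")
    if config.classifier == "mrf":
        fc = config.forest or mrf.MRFConfig(seed=seed)
        if config.forest is not None:
            fc = dataclasses.replace(fc, seed=seed)
        forest = mrf.fit_forest(train, fc)
        labels, _ = mrf.predict(forest, test)
        return labels
    if config.classifier == "nb":
        return baselines.nb_predict(baselines.nb_fit(train), test)
    if config.classifier == "dt":
        return baselines.dt_predict(baselines.dt_fit(train), test)
    if config.classifier == "knn":
        return baselines.knn_predict(train, test, baselines.KNNConfig(k=config.knn_k))
    raise ValueError(f"unknown classifier {config.classifier!r}")


def run_pipeline(table: FeatureTable, config: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Run the full flow on one table and return the evaluation artifacts."""
    try:
        spec = SplitSpec(train_fraction=config.train_fraction,
                         seed=_substream(config.seed, "split"))
        train, test = stratified_split(table, spec)
    except Exception as exc:
        raise StageError("split", exc) from exc

    try:
        params = scale_fit(train)
        train = scale_apply(train, params)
        test = scale_apply(test, params)
    except Exception as exc:
        raise StageError("scale", exc) from exc

    if config.use_extractor:
        try:
            net_cfg = config.network or dna_rcnn.NetworkConfig()
            net_cfg = dataclasses.replace(net_cfg, seed=_substream(config.seed, "extractor"))
            n_classes = int(table.labels.max()) + 1
            network = dna_rcnn.build_network(net_cfg, train.p, n_classes)
            extractor = dna_rcnn.train_extractor(network, train, net_cfg)
            train = dna_rcnn.extract_features(extractor, train)
            test = dna_rcnn.extract_features(extractor, test)
        except Exception as exc:
            raise StageError("extractor", exc) from exc

    n_components = None
    if config.use_pca:
        try:
            model = pca.fit(train, threshold=config.pca_threshold, drop_constant=True)
            train = pca.transform(model, train)
            test = pca.transform(model, test)
            n_components = model.m
        except Exception as exc:
            raise StageError("pca", exc) from exc

    try:
        predictions = _fit_predict(train, test, config)
    except Exception as exc:
        raise StageError("classifier", exc) from exc

    cm = metrics.confusion_matrix(test.labels, predictions)
    report = metrics.macro_report(cm)
    effective = {
        "seed": config.seed,
        "classifier": config.classifier,
        "use_extractor": config.use_extractor,
        "use_pca": config.use_pca,
        "pca_threshold": config.pca_threshold,
        "n_components": n_components,
        "train_fraction": config.train_fraction,
    }
    return PipelineResult(report, cm, predictions, test.labels, n_components, effective)
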