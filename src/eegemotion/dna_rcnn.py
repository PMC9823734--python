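"""Deep normalized attention-residual CNN feature extractor.

The p statistical features of a segment are treated as a length-p,
one-channel 1-D signal.  The trunk is a stack of dense convolutional
blocks — each convolution unit is a same-padded 1-D convolution, a
per-channel activation normalization over positions, and a rectifier, with
outputs concatenated onto the block input so channels grow gradually.  An
attention block then refines the features: a trunk branch produces a
feature map OF, a mask branch (pointwise convolution + sigmoid) produces a
soft mask N in (0, 1), and the two combine by attention-residual learning

    AM = (1 + N) ⊙ OF,

so a zero mask passes the trunk features through unchanged rather than
zeroing them out — the property that lets attention modules stack without
degrading the signal.  (The plain ResNet combination AM = a + OF is
available as the non-attention comparison configuration.)  Global average
pooling, a projection to the embedding dimension, and a softmax
classification head complete the network; after supervised training the
pooled penultimate activations are emitted as extracted features for the
downstream dimensionality-reduction and classification stages.

Training is plain minibatch Adam on multiclass cross-entropy, seeded and
single-threaded, so runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import _autodiff as ad
from .data_io import FeatureTable
from .preprocessing import ShapeError

_NORM_EPS = 1e-5


class DivergenceError(RuntimeError):
    pass


class NetworkConfigError(ValueError):
    pass


def attention_combine(trunk: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Elementwise (1 + N) · OF; a zero mask returns the trunk unchanged."""
    trunk = np.asarray(trunk, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if trunk.shape != mask.shape:
        raise ShapeError(f"trunk {trunk.shape} and mask {mask.shape} differ")
    if mask.min() < 0.0 or mask.max() > 1.0:
        raise ValueError("mask values must lie in [0, 1]")
    return (1.0 + mask) * trunk


def residual_combine(x: np.ndarray, residual: np.ndarray) -> np.ndarray:
    """Plain ResNet combination x + OF(x)."""
    x = np.asarray(x, dtype=float)
    residual = np.asarray(residual, dtype=float)
    if x.shape != residual.shape:
        raise ShapeError(f"input {x.shape} and residual {residual.shape} differ")
    return x + residual


@dataclasses.dataclass(frozen=True)
class NetworkConfig:
    n_dense_blocks: int = 3
    convs_per_block: int = 2
    kernel_width: int = 3
    growth_channels: int = 16
    embedding_dim: int = 64
    epochs: int = 30
    learning_rate: float = 3e-3
    batch_size: int = 32
    seed: int = 0
    attention: bool = True   # False → plain-residual comparison configuration

    def __post_init__(self) -> None:
        positives = (self.n_dense_blocks, self.convs_per_block, self.kernel_width,
                     self.growth_channels, self.embedding_dim, self.epochs,
                     self.batch_size)
        if any(v < 1 for v in positives) or self.learning_rate <= 0:
            raise NetworkConfigError("all size/rate parameters must be positive")
        if self.kernel_width % 2 == 0:
            raise NetworkConfigError("kernel_width must be odd (same padding)")


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Network:
    """Untrained network; parameters live in a flat registry for the optimizer."""

    def __init__(self, config: NetworkConfig, input_width: int, n_classes: int):
        if input_width < config.kernel_width:
            raise NetworkConfigError(
                f"input_width {input_width} smaller than kernel_width {config.kernel_width}")
        self.config = config
        self.input_width = input_width
        self.n_classes = n_classes
        self.params: dict[str, ad.Tensor] = {}
        rng = np.random.default_rng(config.seed)
        k = config.kernel_width

        c_in = 1
        for b in range(config.n_dense_blocks):
            for u in range(config.convs_per_block):
                self._add(f"block{b}_conv{u}_w", _he_init(rng, (config.growth_channels, c_in, k), c_in * k))
                self._add(f"block{b}_conv{u}_b", np.zeros(config.growth_channels))
                c_in += config.growth_channels
        self.trunk_channels = c_in
        # attention block: trunk conv unit (C→C, width k) + pointwise mask conv
        self._add("att_trunk_w", _he_init(rng, (c_in, c_in, k), c_in * k))
        self._add("att_trunk_b", np.zeros(c_in))
        self._add("att_mask_w", _he_init(rng, (c_in, c_in, 1), c_in))
        self._add("att_mask_b", np.zeros(c_in))
        self._add("proj_w", _he_init(rng, (c_in, config.embedding_dim), c_in))
        self._add("proj_b", np.zeros(config.embedding_dim))
        self._add("head_w", _he_init(rng, (config.embedding_dim, n_classes), config.embedding_dim))
        self._add("head_b", np.zeros(n_classes))

    def _add(self, name: str, data: np.ndarray) -> None:
        self.params[name] = ad.Tensor(data)

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # -- forward ------------------------------------------------------------

    def _conv_unit(self, x: ad.Tensor, w: str, b: str) -> ad.Tensor:
        """Convolution + per-channel normalization over positions + relu."""
        h = ad.conv1d(x, self.params[w], self.params[b])
        mu = h.mean(axis=2, keepdims=True)
        d = h - mu
        var = (d * d).mean(axis=2, keepdims=True)
        return (d / (var + _NORM_EPS).sqrt()).relu()

    def forward(self, X: np.ndarray) -> tuple[ad.Tensor, ad.Tensor]:
        """Returns (embedding (B, E), logits (B, n_classes))."""
        cfg = self.config
        x = ad.Tensor(X[:, None, :], requires_grad=False)   # (B, 1, p)
        for b in range(cfg.n_dense_blocks):
            for u in range(cfg.convs_per_block):
                new = self._conv_unit(x, f"block{b}_conv{u}_w", f"block{b}_conv{u}_b")
                x = ad.concat([x, new], axis=1)
        trunk = self._conv_unit(x, "att_trunk_w", "att_trunk_b")
        mask = ad.conv1d(x, self.params["att_mask_w"], self.params["att_mask_b"]).sigmoid()
        if cfg.attention:
            combined = (mask + 1.0) * trunk          # AM = (1 + N) ⊙ OF
        else:
            combined = x + trunk                     # plain residual path
        pooled = ad.global_avg_pool(combined)        # (B, C)
        embedding = (pooled.matmul(self.params["proj_w"]) + self.params["proj_b"]).relu()
        logits = embedding.matmul(self.params["head_w"]) + self.params["head_b"]
        return embedding, logits


@dataclasses.dataclass
class TrainedExtractor:
    network: Network
    config: NetworkConfig
    input_width: int
    loss_history: list[float]

    @property
    def embedding_dim(self) -> int:
        return self.config.embedding_dim


def build_network(config: NetworkConfig, input_width: int, n_classes: int) -> Network:
    return Network(config, input_width, n_classes)


def train_extractor(network: Network, train: FeatureTable,
                    config: "NetworkConfig | None" = None) -> TrainedExtractor:
    """Fit by minibatch Adam on multiclass cross-entropy.

    Raises DivergenceError naming the epoch if the loss goes non-finite.
    """
    config = config or network.config
    X, y = train.values, train.labels
    if X.shape[1] != network.input_width:
        raise ShapeError(f"training width {X.shape[1]} != network input {network.input_width}")
    rng = np.random.default_rng(config.seed + 1)
    opt = ad.Adam(list(network.params.values()), lr=config.learning_rate)
    history: list[float] = []
    n = len(y)
    for epoch in range(config.epochs):
        perm = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = perm[start:start + config.batch_size]
            _, logits = network.forward(X[idx])
            loss = ad.cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
        history.append(epoch_loss / n)
    return TrainedExtractor(network, config, network.input_width, history)


def extract_features(model: TrainedExtractor, table: FeatureTable) -> FeatureTable:
    """Pooled penultimate activations as a new feature table; labels kept."""
    if table.p != model.input_width:
        raise ShapeError(f"table width {table.p} != extractor input {model.input_width}")
    embedding, _ = model.network.forward(table.values)
    names = [f"emb_{j:03d}" for j in range(model.embedding_dim)]
    return table.with_values(embedding.data, names)


def predict(model: TrainedExtractor, table: FeatureTable) -> np.ndarray:
    """Head argmax; used for the extractor's own training diagnostics."""
    _, logits = model.network.forward(table.values)
    return np.argmax(logits.data, axis=1)


def save_extractor(model: TrainedExtractor, path: "str | Path") -> None:
    arrays = {name: p.data for name, p in model.network.params.items()}
    meta = dict(dataclasses.asdict(model.config),
                input_width=model.input_width,
                n_classes=model.network.n_classes,
                loss_history=model.loss_history)
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_extractor(path: "str | Path") -> TrainedExtractor:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    input_width = meta.pop("input_width")
    n_classes = meta.pop("n_classes")
    history = meta.pop("loss_history")
    config = NetworkConfig(**meta)
    network = Network(config, input_width, n_classes)
    for name in network.params:
        network.params[name].data = archive[name]
    return TrainedExtractor(network, config, input_width, history)
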