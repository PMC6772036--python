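"""The CNN tile-classifier harness.

Two-class head on a compact convolutional backbone, imbalance-aware weighted
batch sampling, SGD with momentum and a step-decayed learning rate, per-epoch
evaluation against a held-out set, and tile-level inference producing
(p_water, p_whale) probability vectors.

The shipped backbone is ``smallnet`` — three 3x3 conv/ReLU/max-pool blocks
followed by a small dense head — trainable from scratch on one CPU in
minutes. The torchvision family names (resnet18/34/152, densenet) are
recognised in :class:`TrainConfig` but require the optional torch backend and
raise :class:`UnsupportedArchitectureError` in this build; likewise
``pretrained=True`` raises because no pretrained weights ship with smallnet.

Determinism: one master seed fans out to weight init and batch sampling, so
identical (data, config) runs give bit-identical parameter trajectories on a
given platform (floating-point reductions can differ across BLAS builds).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import TileDataset, WHALE, WATER
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    ParameterError,
    PretrainedWeightsUnavailableError,
    UnsupportedArchitectureError,
)
from .metrics import ConfusionMatrix, MetricReport, confusion
from .nnet import Conv3x3, Dense, Flatten, MaxPool2, ReLU, SGDMomentum, Sequential, cross_entropy, softmax

__all__ = [
    "TrainConfig",
    "EpochMetrics",
    "PredictionVector",
    "ModelHandle",
    "TrainResult",
    "build_model",
    "sample_weights",
    "tile_weights",
    "lr_at_epoch",
    "train",
    "select_best_epoch",
    "predict",
    "predict_dataset",
]

_ARCHITECTURES = ("resnet18", "resnet34", "resnet152", "densenet", "smallnet")
_TORCH_BACKBONES = ("resnet18", "resnet34", "resnet152", "densenet")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run.

    Defaults mirror the reference protocol for fine-tuning a pretrained
    backbone: base learning rate 0.0006 decayed by ``decay_factor`` every
    ``step_size_epochs`` (step size 7), momentum 0.9, 24 epochs, batch sizes
    in the small-batch regime (4-32), weighted sampling against class
    imbalance, and 224 px inputs. ``smallnet`` runs typically override
    ``input_px`` (32) and the learning rate, since a from-scratch compact
    net wants a larger step than a fine-tuned deep one.
    """

    architecture: str = "smallnet"
    pretrained: bool = False
    learning_rate: float = 0.0006
    momentum: float = 0.9
    step_size_epochs: int = 7
    decay_factor: float = 0.1
    batch_size: int = 16
    n_epochs: int = 24
    sampler: str = "weighted"
    input_px: int = 224
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in _ARCHITECTURES:
            raise UnsupportedArchitectureError(
                f"unknown architecture {self.architecture!r}; "
                f"supported: {_ARCHITECTURES}"
            )
        if self.learning_rate < 0:
            raise ParameterError("learning_rate must be >= 0")
        if not 0 <= self.momentum < 1:
            raise ParameterError("momentum must lie in [0, 1)")
        if self.step_size_epochs < 1:
            raise ParameterError("step_size_epochs must be >= 1")
        if not 0 < self.decay_factor <= 1:
            raise ParameterError("decay_factor must lie in (0, 1]")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.n_epochs < 1:
            raise ParameterError("n_epochs must be >= 1")
        if self.sampler not in ("weighted", "uniform"):
            raise ParameterError("sampler must be 'weighted' or 'uniform'")
        if self.input_px < 8 or self.input_px % 8:
            raise ParameterError("input_px must be a positive multiple of 8")


@dataclass(frozen=True)
class EpochMetrics:
    """Per-epoch training trace plus held-out water-positive metrics."""

    epoch: int  # 1-based
    train_accuracy: float
    train_loss: float
    precision: float | None
    recall: float | None
    f1: float | None

    def __post_init__(self) -> None:
        if not 0 <= self.train_accuracy <= 1:
            raise ParameterError("train_accuracy must lie in [0, 1]")
        if self.train_loss < 0:
            raise ParameterError("train_loss must be >= 0")


@dataclass(frozen=True)
class PredictionVector:
    """Softmax output for one tile; p_water + p_whale = 1."""

    p_water: float
    p_whale: float

    @property
    def hard_label(self) -> str:
        """whale iff p_whale > 0.5; the tie goes to water so a degenerate
        model does not flood the review queue."""
        return WHALE if self.p_whale > 0.5 else WATER


@dataclass
class ModelHandle:
    """A built model plus the input-normalisation statistics it expects."""

    net: Sequential
    config: TrainConfig
    norm_mean: np.ndarray = field(
        default_factory=lambda: np.full(3, 0.5, dtype=np.float32)
    )
    norm_std: np.ndarray = field(
        default_factory=lambda: np.full(3, 0.25, dtype=np.float32)
    )
    trained: bool = False


def build_model(config: TrainConfig) -> ModelHandle:
    """Build a two-logit classifier for the configured backbone.

    The final layer always outputs exactly 2 logits. ``pretrained=True``
    raises explicitly (no silent random fallback).
    """
    if config.architecture in _TORCH_BACKBONES:
        raise UnsupportedArchitectureError(
            f"{config.architecture!r} requires the optional torch/torchvision "
            "backend, which is not part of this build; use 'smallnet'"
        )
    if config.pretrained:
        raise PretrainedWeightsUnavailableError(
            "no pretrained weights are available for 'smallnet'; "
            "set pretrained=False"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    px = config.input_px
    feat = (px // 8) ** 2 * 32
    net = Sequential(
        [
            Conv3x3(3, 8, rng),
            ReLU(),
            MaxPool2(),
            Conv3x3(8, 16, rng),
            ReLU(),
            MaxPool2(),
            Conv3x3(16, 32, rng),
            ReLU(),
            MaxPool2(),
            Flatten(),
            Dense(feat, 64, rng),
            ReLU(),
            Dense(64, 2, rng),
        ]
    )
    return ModelHandle(net=net, config=config)


def sample_weights(counts: dict[str, int]) -> dict[str, float]:
    """Inverse-frequency per-tile sampling weight for each class.

    Every tile of class c gets weight 1/counts[c]; sampling with replacement
    under these weights makes the expected whale share of any batch 1/2.
    """
    for cls in (WHALE, WATER):
        if counts.get(cls, 0) <= 0:
            raise DegenerateInputError(f"empty class {cls!r}")
    return {cls: 1.0 / counts[cls] for cls in (WHALE, WATER)}


def tile_weights(labels: list[str], counts: dict[str, int] | None = None) -> np.ndarray:
    """Per-tile weight vector (normalised to sum 1) from class labels."""
    if counts is None:
        counts = {WHALE: labels.count(WHALE), WATER: labels.count(WATER)}
    w = sample_weights(counts)
    arr = np.array([w[lab] for lab in labels], dtype=np.float64)
    return arr / arr.sum()


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Step-decay schedule: base * decay^floor((epoch - 1)/step), epoch 1-based."""
    if epoch < 1:
        raise ParameterError("epoch is 1-based")
    return config.learning_rate * config.decay_factor ** (
        (epoch - 1) // config.step_size_epochs
    )


@dataclass
class TrainResult:
    """Per-epoch metrics, checkpoints, and the realised LR / batch trace."""

    epoch_metrics: list[EpochMetrics]
    checkpoints: list[list[np.ndarray]]
    lr_trace: list[float]
    batch_whale_share: list[float]  # realised whale fraction per epoch

    def restore(self, model: ModelHandle, epoch: int) -> None:
        """Load the parameters saved at the end of a (1-based) epoch."""
        if not 1 <= epoch <= len(self.checkpoints):
            raise ParameterError(f"no checkpoint for epoch {epoch}")
        model.net.load_state(self.checkpoints[epoch - 1])


def _normalize(model: ModelHandle, X: np.ndarray) -> np.ndarray:
    return (X - model.norm_mean[None, :, None, None]) / model.norm_std[
        None, :, None, None
    ]


def train(
    model: ModelHandle,
    train_set: TileDataset,
    eval_set: TileDataset,
    config: TrainConfig | None = None,
) -> TrainResult:
    """Train for ``n_epochs`` with per-epoch held-out evaluation.

    Cross-entropy on the 2-class output, SGD with momentum, learning rate
    multiplied by ``decay_factor`` every ``step_size_epochs``. The sampler
    draws one epoch's worth of tiles with replacement under inverse-frequency
    weights ("weighted") or a plain permutation ("uniform"). Every epoch ends
    with a checkpoint and a water-positive evaluation on ``eval_set``.
    """
    config = config or model.config
    X, y = train_set.to_arrays(input_px=config.input_px)
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("training set must contain both classes")
    Xe, ye = eval_set.to_arrays(input_px=config.input_px)
    eval_labels = [WATER if v == 0 else WHALE for v in ye]

    # Per-dataset channel statistics (no pretrained stats in this build).
    model.norm_mean = X.mean(axis=(0, 2, 3)).astype(np.float32)
    model.norm_std = np.maximum(X.std(axis=(0, 2, 3)), 1e-6).astype(np.float32)
    Xn = _normalize(model, X).astype(np.float32)

    labels = [WATER if v == 0 else WHALE for v in y]
    weights = tile_weights(labels) if config.sampler == "weighted" else None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xBA7C4]))

    n = len(y)
    opt = SGDMomentum(model.net.params(), lr=config.learning_rate, momentum=config.momentum)
    result = TrainResult([], [], [], [])

    for epoch in range(1, config.n_epochs + 1):
        lr = lr_at_epoch(config, epoch)
        opt.lr = lr
        result.lr_trace.append(lr)

        if weights is not None:
            order = rng.choice(n, size=n, replace=True, p=weights)
        else:
            order = rng.permutation(n)

        losses, correct, seen, whale_seen = [], 0, 0, 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xn[idx], y[idx]
            logits = model.net.forward(xb)
            loss, grad = cross_entropy(logits, yb)
            if lr > 0:
                model.net.backward(grad)
                opt.step()
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
            seen += len(idx)
            whale_seen += int((yb == 1).sum())

        result.batch_whale_share.append(whale_seen / seen)
        result.checkpoints.append(model.net.state())

        cm = _eval_confusion(model, Xe, eval_labels)
        rep = MetricReport.from_confusion(cm)
        result.epoch_metrics.append(
            EpochMetrics(
                epoch=epoch,
                train_accuracy=correct / seen,
                train_loss=sum(losses) / seen,
                precision=rep.precision,
                recall=rep.recall,
                f1=rep.f1,
            )
        )
    model.trained = True
    return result


def _eval_confusion(
    model: ModelHandle, Xn_raw: np.ndarray, labels: list[str]
) -> ConfusionMatrix:
    preds = [pv.hard_label for pv in predict(model, Xn_raw)]
    return confusion(labels, preds, positive_class=WATER)


def select_best_epoch(metrics: list[EpochMetrics], criterion: str = "f1") -> int:
    """1-based epoch maximising the criterion; ties and undefined values
    resolve to the earliest epoch."""
    if not metrics:
        raise ParameterError("empty metrics list")
    if criterion not in ("f1", "precision", "recall", "train_accuracy"):
        raise ConfigurationError(f"unknown criterion {criterion!r}")
    best_epoch, best_val = metrics[0].epoch, -1.0
    for m in metrics:
        val = getattr(m, criterion)
        val = -1.0 if val is None else val
        if val > best_val:
            best_val, best_epoch = val, m.epoch
    return best_epoch


def _as_input_array(model: ModelHandle, tiles) -> np.ndarray:
    if isinstance(tiles, TileDataset):
        X, _ = tiles.to_arrays(input_px=model.config.input_px)
        return X
    X = np.asarray(tiles, dtype=np.float32)
    if X.ndim == 3:
        X = X[None]
    if X.ndim != 4 or X.shape[1] != 3:
        raise ParameterError("expected (N, 3, px, px) tile array")
    if X.shape[2] != model.config.input_px or X.shape[3] != model.config.input_px:
        raise ParameterError(
            f"tiles are {X.shape[2]}x{X.shape[3]} px but the model expects "
            f"{model.config.input_px}; upscale upstream"
        )
    return X


def predict(
    model: ModelHandle, tiles, batch_size: int = 256
) -> list[PredictionVector]:
    """Probability vectors for tiles (a TileDataset or (N, 3, px, px) array).

    Hard labels are available on each vector: whale iff p_whale > 0.5, ties
    to water.
    """
    X = _as_input_array(model, tiles)
    out: list[PredictionVector] = []
    for start in range(0, len(X), batch_size):
        xb = _normalize(model, X[start : start + batch_size]).astype(np.float32)
        probs = softmax(model.net.forward(xb).astype(np.float64))
        out.extend(
            PredictionVector(p_water=float(p[0]), p_whale=float(p[1])) for p in probs
        )
    return out


def predict_dataset(
    model: ModelHandle, dataset: TileDataset
) -> tuple[list[PredictionVector], ConfusionMatrix]:
    """Predict a labeled dataset and return the water-positive confusion."""
    vectors = predict(model, dataset)
    preds = [v.hard_label for v in vectors]
    return vectors, confusion(dataset.labels(), preds, positive_class=WATER)
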