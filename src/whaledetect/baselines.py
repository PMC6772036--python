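"""Classical comparators: HOG features feeding a ridge-regression classifier
or a C-support-vector classifier.

Both baselines consume the same labeled tile datasets and report through the
same water-positive metrics path as the CNN, so comparisons never drift on
conventions. Features are histograms of oriented gradients over the
luminance channel; defaults follow the canonical detector configuration
(8 px cells, 2x2 blocks, 9 unsigned orientation bins). Baselines operate on
the native 32 px tiles — interpolation to 224 px adds no gradient
information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import hog as _sk_hog
from sklearn.linear_model import Ridge
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .datasets import TileDataset, WATER, WHALE
from .errors import DegenerateInputError, ParameterError
from .metrics import ConfusionMatrix, confusion

__all__ = [
    "HogParams",
    "BaselineConfig",
    "BaselineModel",
    "hog_features",
    "hog_dataset_features",
    "fit_baseline",
    "evaluate_baseline",
]

#: Rec. 709 luminance weights used for the grayscale conversion.
LUMINANCE_WEIGHTS = (0.2126, 0.7152, 0.0722)


@dataclass(frozen=True)
class HogParams:
    """HOG descriptor configuration."""

    cell_px: int = 8
    block_cells: int = 2
    n_orientations: int = 9
    signed: bool = False

    def __post_init__(self) -> None:
        if self.cell_px < 1 or self.block_cells < 1 or self.n_orientations < 1:
            raise ParameterError("HOG parameters must be positive")

    def descriptor_length(self, tile_px: int) -> int:
        """Closed-form descriptor length for a square tile."""
        if tile_px % self.cell_px:
            raise ParameterError(
                f"tile size {tile_px} not divisible into {self.cell_px}px cells"
            )
        cells = tile_px // self.cell_px
        blocks = cells - self.block_cells + 1
        if blocks < 1:
            raise ParameterError("tile too small for the block size")
        return blocks**2 * self.block_cells**2 * self.n_orientations


@dataclass(frozen=True)
class BaselineConfig:
    """Which classical model to fit and its single regularisation knob."""

    model: str = "ridge"
    alpha: float = 1.0  # ridge L2 penalty
    C: float = 1.0  # C-SVC penalty
    kernel: str = "rbf"  # C-SVC kernel; "linear" selectable
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("ridge", "c_svc"):
            raise ParameterError(f"unknown baseline model {self.model!r}")
        if self.alpha < 0:
            raise ParameterError("alpha must be >= 0")
        if not self.C > 0:
            raise ParameterError("C must be > 0")


def _to_gray(tile_pixels: np.ndarray) -> np.ndarray:
    w = np.asarray(LUMINANCE_WEIGHTS)
    return tile_pixels @ w


def hog_features(tile_pixels: np.ndarray, params: HogParams | None = None) -> np.ndarray:
    """HOG descriptor of one tile (H x W x 3 or H x W, float in [0, 1]).

    Deterministic; length equals ``params.descriptor_length(tile_px)``;
    blocks are L2-Hys normalised (unit-capped magnitude).
    """
    params = params or HogParams()
    img = np.asarray(tile_pixels, dtype=np.float64)
    if img.ndim == 3:
        img = _to_gray(img)
    if img.shape[0] != img.shape[1]:
        raise ParameterError("tiles must be square")
    expected = params.descriptor_length(img.shape[0])
    desc = _sk_hog(
        img,
        orientations=params.n_orientations,
        pixels_per_cell=(params.cell_px, params.cell_px),
        cells_per_block=(params.block_cells, params.block_cells),
        block_norm="L2-Hys",
        feature_vector=True,
    )
    if desc.shape[0] != expected:
        raise ParameterError(
            f"descriptor length {desc.shape[0]} != closed form {expected}"
        )
    return desc


def hog_dataset_features(
    dataset: TileDataset, params: HogParams | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Stack HOG descriptors of all retained tiles; y is 0=water, 1=whale."""
    params = params or HogParams()
    feats, ys = [], []
    for t in dataset.retained:
        feats.append(hog_features(t.tile.pixels, params))
        ys.append(1 if t.label == WHALE else 0)
    if not feats:
        raise DegenerateInputError("empty dataset")
    return np.asarray(feats), np.asarray(ys, dtype=np.int64)


@dataclass
class BaselineModel:
    """A fitted classical baseline (estimator + its configuration)."""

    config: BaselineConfig
    estimator: Pipeline
    kind: str

    def predict_labels(self, features: np.ndarray) -> list[str]:
        if self.kind == "ridge":
            scores = self.estimator.predict(features)  # (n, 2) one-hot targets
            # whale only if strictly ahead; ties go to water.
            return [WHALE if s[1] > s[0] else WATER for s in scores]
        preds = self.estimator.predict(features)
        return [WHALE if p == 1 else WATER for p in preds]


def fit_baseline(
    features: np.ndarray, labels: np.ndarray, config: BaselineConfig | None = None
) -> BaselineModel:
    """Fit ridge (one-hot L2-penalised regression + argmax) or C-SVC.

    Ridge classifies via linear regression onto one-hot class targets with
    penalty alpha; C-SVC is a soft-margin maximum-margin classifier with
    penalty C and an RBF kernel by default (scale-heuristic bandwidth).
    Deterministic per seed. Both classes must be present and features finite.
    """
    config = config or BaselineConfig()
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.all(np.isfinite(features)):
        raise DegenerateInputError("non-finite feature values")
    if len(np.unique(labels)) < 2:
        raise DegenerateInputError("both classes must be present")

    if config.model == "ridge":
        onehot = np.eye(2)[labels]
        est = Pipeline(
            [
                ("scale", StandardScaler()),
                ("ridge", Ridge(alpha=config.alpha)),
            ]
        )
        est.fit(features, onehot)
        return BaselineModel(config=config, estimator=est, kind="ridge")

    est = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "svc",
                SVC(
                    C=config.C,
                    kernel=config.kernel,
                    gamma="scale",
                    random_state=config.seed,
                ),
            ),
        ]
    )
    est.fit(features, labels)
    return BaselineModel(config=config, estimator=est, kind="c_svc")


def evaluate_baseline(
    model: BaselineModel,
    eval_features: np.ndarray,
    eval_labels: np.ndarray,
) -> ConfusionMatrix:
    """Water-positive confusion matrix on an evaluation set (same metrics
    path as the CNN)."""
    truth = [WHALE if v == 1 else WATER for v in np.asarray(eval_labels)]
    preds = model.predict_labels(np.asarray(eval_features))
    return confusion(truth, preds, positive_class=WATER)
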