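"""Turn tiled scenes into labeled datasets.

Implements the labeling conventions of the detection pipeline:

* a tile's ``whale_fraction`` is, per instance, the fraction of that whale's
  total mask pixels that fall inside the tile (NOT the fraction of the tile
  covered); the tile records the maximum over instances;
* the retention rule: tiles with fraction 0 are water; tiles holding at
  least ``retention_threshold`` (default 20%) of some whale are whale tiles;
  sliver tiles in between are excluded from BOTH classes (retained=False),
  since the whale is better captured by a neighbouring tile;
* stratified train/test splitting (90/10 by default via 10 folds), with the
  split unit either the frame (default) or the individual — the latter keeps
  all duplicate frames of one whale in a single fold so duplicates can never
  leak between train and test;
* class subsampling (e.g. the n = 1,390 water test subset) and the balanced
  subset used by the classical baselines (all whale tiles plus an equal
  number of random water tiles).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, ParameterError
from .prep import Tile, upscale_tile
from .scenes import WhaleInstance

__all__ = [
    "LabeledTile",
    "TileDataset",
    "FoldSpec",
    "whale_fraction",
    "assign_labels",
    "subsample_class",
    "make_folds",
    "balanced_subset",
    "WHALE",
    "WATER",
]

WHALE = "whale"
WATER = "water"


@dataclass
class LabeledTile:
    """A tile with its class label and retention bookkeeping.

    ``whale_fraction`` is the per-instance maximum fraction of a whale lying
    in this tile; ``individual_id`` is the individual owning that maximum
    (None for water tiles). ``retained=False`` marks sliver tiles excluded
    from both classes.
    """

    tile: Tile
    label: str
    whale_fraction: float
    retained: bool
    individual_id: int | None = None

    @property
    def tile_id(self) -> str:
        return self.tile.tile_id


@dataclass
class TileDataset:
    """A collection of labeled tiles with class counts over retained tiles."""

    tiles: list[LabeledTile] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.tile_id for t in self.tiles]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate tile ids in dataset")

    @property
    def retained(self) -> list[LabeledTile]:
        return [t for t in self.tiles if t.retained]

    @property
    def counts(self) -> dict[str, int]:
        c = {WHALE: 0, WATER: 0}
        for t in self.retained:
            c[t.label] += 1
        return c

    def __len__(self) -> int:
        return len(self.retained)

    def subset(self, tile_ids: set[str]) -> "TileDataset":
        return TileDataset(
            tiles=[t for t in self.tiles if t.retained and t.tile_id in tile_ids],
            provenance=dict(self.provenance, subset_of=len(self)),
        )

    def to_arrays(self, input_px: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Stack retained tiles into (N, 3, px, px) float32 X and int y
        (0 = water, 1 = whale), optionally upscaling each tile first."""
        xs, ys = [], []
        for t in self.retained:
            tile = t.tile
            if input_px is not None and input_px != tile.tile_px:
                tile = upscale_tile(tile, input_px)
            xs.append(np.moveaxis(tile.pixels, 2, 0))
            ys.append(1 if t.label == WHALE else 0)
        if not xs:
            raise DegenerateInputError("empty dataset")
        return (
            np.asarray(xs, dtype=np.float32),
            np.asarray(ys, dtype=np.int64),
        )

    def labels(self) -> list[str]:
        return [t.label for t in self.retained]

    def to_manifest(self) -> pd.DataFrame:
        rows = [
            {
                "tile_id": t.tile_id,
                "scene_id": t.tile.parent_scene_id,
                "row": t.tile.grid_pos[0],
                "col": t.tile.grid_pos[1],
                "label": t.label,
                "whale_fraction": t.whale_fraction,
                "retained": t.retained,
                "individual_id": -1 if t.individual_id is None else t.individual_id,
            }
            for t in self.tiles
        ]
        return pd.DataFrame(rows)


def whale_fraction(
    tile_bounds: tuple[int, int, int, int], instance: WhaleInstance
) -> float:
    """Fraction of one whale's total mask coverage lying inside a tile.

    ``tile_bounds`` are half-open pixel bounds (r0, r1, c0, c1). Works for
    binary and fractional-coverage masks alike (sums coverage).
    """
    total = instance.total_pixels
    if total <= 0:
        raise DegenerateInputError(
            f"instance {instance.instance_id} has an empty mask"
        )
    r0, r1, c0, c1 = tile_bounds
    inside = float(instance.mask[r0:r1, c0:c1].sum())
    return inside / total


def assign_labels(
    tiles: list[Tile],
    instances: list[WhaleInstance],
    retention_threshold: float = 0.20,
) -> list[LabeledTile]:
    """Label tiles as whale/water and apply the sliver-retention rule.

    fraction = 0 -> water; fraction >= threshold -> whale ("at least 20% of
    the whale remained in the tile", boundary inclusive); 0 < fraction <
    threshold -> excluded from both classes (retained=False). The result is
    independent of tile enumeration order.
    """
    if not 0 < retention_threshold <= 1:
        raise ParameterError("retention_threshold must lie in (0, 1]")
    labeled: list[LabeledTile] = []
    for tile in tiles:
        r0, c0 = tile.origin_px
        bounds = (r0, r0 + tile.tile_px, c0, c0 + tile.tile_px)
        best_frac = 0.0
        best_ind: int | None = None
        for inst in instances:
            frac = whale_fraction(bounds, inst)
            if frac > best_frac:
                best_frac = frac
                best_ind = inst.individual_id
        if best_frac == 0.0:
            labeled.append(LabeledTile(tile, WATER, 0.0, True, None))
        elif best_frac >= retention_threshold:
            labeled.append(LabeledTile(tile, WHALE, best_frac, True, best_ind))
        else:
            labeled.append(LabeledTile(tile, WHALE, best_frac, False, best_ind))
    return labeled


def subsample_class(
    dataset: TileDataset, label: str, n: int, seed: int = 0
) -> TileDataset:
    """Uniformly subsample one class without replacement; the other class is
    untouched. Deterministic per seed."""
    if label not in (WHALE, WATER):
        raise ParameterError(f"unknown class {label!r}")
    members = [t for t in dataset.retained if t.label == label]
    others = [t for t in dataset.retained if t.label != label]
    if n > len(members):
        raise ParameterError(
            f"cannot sample {n} of {len(members)} {label} tiles"
        )
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(members), size=n, replace=False)
    kept = [members[i] for i in sorted(keep_idx)]
    return TileDataset(
        tiles=others + kept,
        provenance=dict(dataset.provenance, subsampled={label: n, "seed": seed}),
    )


@dataclass(frozen=True)
class FoldSpec:
    """A stratified k-fold partition of a dataset.

    ``assignments`` maps tile_id -> fold index in [0, n_folds). With
    ``unit="individual"`` all duplicate frames of one whale share a fold.
    """

    n_folds: int
    assignments: dict[str, int]
    unit: str
    seed: int

    def split(self, dataset: TileDataset, fold: int) -> tuple[TileDataset, TileDataset]:
        """(train, test) datasets for one fold; test = that fold's tiles."""
        if not 0 <= fold < self.n_folds:
            raise ParameterError(f"fold {fold} outside 0..{self.n_folds - 1}")
        test_ids = {tid for tid, f in self.assignments.items() if f == fold}
        train_ids = set(self.assignments) - test_ids
        return dataset.subset(train_ids), dataset.subset(test_ids)


def make_folds(
    dataset: TileDataset,
    n_folds: int = 10,
    unit: str = "frame",
    seed: int = 0,
) -> FoldSpec:
    """Stratified k-fold assignment (default 10 folds, i.e. 90/10 splits).

    unit="frame" shuffles tiles freely within each class, giving per-fold
    class counts that differ by at most 1. unit="individual" assigns whole
    individuals (all duplicate frames) greedily to the currently smallest
    fold, preventing duplicate-frame leakage at the cost of slightly less
    even counts.
    """
    if n_folds < 2:
        raise ParameterError("n_folds must be >= 2")
    if unit not in ("frame", "individual"):
        raise ParameterError(f"unknown fold unit {unit!r}")
    counts = dataset.counts
    for cls, cnt in counts.items():
        if cnt < n_folds and cnt > 0:
            raise ParameterError(
                f"class {cls!r} has {cnt} tiles, fewer than {n_folds} folds"
            )

    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}

    water = [t for t in dataset.retained if t.label == WATER]
    whale = [t for t in dataset.retained if t.label == WHALE]

    def _assign_frames(tiles: list[LabeledTile]) -> None:
        order = rng.permutation(len(tiles))
        for pos, idx in enumerate(order):
            assignments[tiles[idx].tile_id] = pos % n_folds

    _assign_frames(water)
    if unit == "frame":
        _assign_frames(whale)
    else:
        groups: dict[int | str, list[LabeledTile]] = {}
        for t in whale:
            key = t.individual_id if t.individual_id is not None else t.tile_id
            groups.setdefault(key, []).append(t)
        keys = sorted(groups, key=lambda k: (-len(groups[k]), str(k)))
        # Shuffle ties deterministically so folds differ across seeds.
        keys = [keys[i] for i in rng.permutation(len(keys))]
        keys.sort(key=lambda k: -len(groups[k]))
        fold_sizes = [0] * n_folds
        for key in keys:
            fold = int(np.argmin(fold_sizes))
            for t in groups[key]:
                assignments[t.tile_id] = fold
            fold_sizes[fold] += len(groups[key])

    return FoldSpec(n_folds=n_folds, assignments=assignments, unit=unit, seed=seed)


def balanced_subset(dataset: TileDataset, seed: int = 0) -> TileDataset:
    """All whale tiles plus an equal number of uniformly sampled water tiles
    (the training set used for the classical baselines)."""
    counts = dataset.counts
    if counts[WHALE] > counts[WATER]:
        raise ParameterError(
            f"whale count {counts[WHALE]} exceeds water count {counts[WATER]}"
        )
    return subsample_class(dataset, WATER, counts[WHALE], seed=seed)
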