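"""Labeling, the 20%-retention rule, subsampling, folds, balanced subsets."""

import numpy as np
import pytest

from whaledetect.datasets import (
    LabeledTile,
    TileDataset,
    WATER,
    WHALE,
    assign_labels,
    balanced_subset,
    make_folds,
    subsample_class,
    whale_fraction,
)
from whaledetect.errors import DegenerateInputError, ParameterError
from whaledetect.prep import Tile, TileGrid, tile_scene
from whaledetect.scenes import SceneParams, WhaleInstance, generate_scene


def _instance(mask, instance_id=0, individual_id=0):
    return WhaleInstance(
        instance_id=instance_id,
        mask=np.asarray(mask),
        length_m=8.0,
        pose_deg=0.0,
        individual_id=individual_id,
    )


def _dummy_tile(tile_id_parts, px=1):
    scene, row, col = tile_id_parts
    return Tile(np.zeros((px, px, 3)), (row, col), scene, 0.31, (row * px, col * px))


def _dataset(n_whale, n_water, px=1):
    """Synthetic dataset of dummy tiles with the requested class counts."""
    tiles = []
    for i in range(n_whale):
        tiles.append(
            LabeledTile(_dummy_tile(("w", i, 0), px), WHALE, 1.0, True, i)
        )
    for i in range(n_water):
        tiles.append(LabeledTile(_dummy_tile(("o", i, 1), px), WATER, 0.0, True))
    return TileDataset(tiles=tiles)


# -------------------------------------------------------------- whale_fraction
def test_whale_fraction_inside_outside():
    mask = np.zeros((8, 8), dtype=bool)
    mask[1:3, 1:3] = True
    inst = _instance(mask)
    assert whale_fraction((0, 4, 0, 4), inst) == 1.0
    assert whale_fraction((4, 8, 4, 8), inst) == 0.0


def test_whale_fraction_straddling_tiles_sums_to_one():
    scene = generate_scene(
        SceneParams(
            width_px=96, height_px=96, gsd_m=0.31, n_whales=2, seed=21, sea_state=1
        )
    )
    grid = TileGrid.for_shape(scene.shape, 32)
    for inst in scene.whales:
        total = sum(
            whale_fraction(grid.bounds(r, c), inst)
            for r in range(grid.n_rows)
            for c in range(grid.n_cols)
        )
        # Grid covers the whole 96x96 scene, so fractions partition the mask.
        assert total == pytest.approx(1.0, abs=1e-12)


def test_whale_fraction_empty_mask_rejected():
    with pytest.raises(DegenerateInputError):
        whale_fraction((0, 4, 0, 4), _instance(np.zeros((8, 8), dtype=bool)))


# -------------------------------------------------------------- assign_labels
def _tiles_for_boundary(split_rows):
    """A 100-px whale mask on a 10x20 scene cut by the tile border at col 10
    so exactly ``split_rows`` rows' worth of pixels lie in the left tile."""
    mask = np.zeros((10, 20), dtype=bool)
    mask[:, 10 - split_rows : 10 - split_rows + 10] = False
    # 100 whale pixels in a 10x10 block positioned so split_rows*10 pixels
    # fall left of column 10.
    mask[:10, 10 - split_rows : 20 - split_rows] = True
    left = Tile(np.zeros((10, 10, 3)), (0, 0), "s", 0.31, (0, 0))
    right = Tile(np.zeros((10, 10, 3)), (0, 1), "s", 0.31, (0, 10))
    return [left, right], [_instance(mask)]


def test_retention_boundary_inclusive_at_threshold():
    # 19% of the whale in the left tile -> excluded; 20% -> whale.
    tiles, instances = _tiles_for_boundary(2)
    labeled = assign_labels(tiles, instances)
    left = [t for t in labeled if t.tile.grid_pos == (0, 0)][0]
    assert left.whale_fraction == pytest.approx(0.2)
    assert left.label == WHALE and left.retained

    # 100-pixel whale with exactly 19 pixels left of the tile border.
    mask19 = np.zeros((10, 20), dtype=bool)
    mask19[0:10, 9] = True  # 10 px in col 9
    mask19[0:9, 8] = True  # 9 px in col 8
    mask19[0:10, 10:18] = True  # 80 px right of the border
    mask19[0, 18] = True  # +1 -> 100 total
    tiles = [
        Tile(np.zeros((10, 10, 3)), (0, 0), "s", 0.31, (0, 0)),
        Tile(np.zeros((10, 10, 3)), (0, 1), "s", 0.31, (0, 10)),
    ]
    labeled = assign_labels(tiles, [_instance(mask19)])
    left = [t for t in labeled if t.tile.grid_pos == (0, 0)][0]
    assert left.whale_fraction == pytest.approx(19 / 100)
    assert not left.retained  # sliver tile: excluded from both classes


def test_all_water_scene_has_no_exclusions():
    scene = generate_scene(
        SceneParams(width_px=96, height_px=96, gsd_m=0.31, n_whales=0, seed=2)
    )
    labeled = assign_labels(tile_scene(scene), scene.whales)
    assert all(t.label == WATER and t.retained for t in labeled)


def test_assign_labels_order_invariant():
    scene = generate_scene(
        SceneParams(width_px=128, height_px=128, gsd_m=0.31, n_whales=2, seed=9)
    )
    tiles = tile_scene(scene)
    a = assign_labels(tiles, scene.whales)
    b = assign_labels(list(reversed(tiles)), scene.whales)
    by_id = {t.tile_id: (t.label, t.retained, t.whale_fraction) for t in b}
    for t in a:
        assert by_id[t.tile_id] == (t.label, t.retained, t.whale_fraction)


def test_assign_labels_threshold_validation():
    with pytest.raises(ParameterError):
        assign_labels([], [], retention_threshold=0.0)
    with pytest.raises(ParameterError):
        assign_labels([], [], retention_threshold=1.5)


@pytest.mark.parametrize("seed", range(20))
def test_labels_match_mask_pixel_brute_force(seed):
    """Label/retention of every tile equals a brute-force recomputation from
    the instance masks."""
    scene = generate_scene(
        SceneParams(
            width_px=96,
            height_px=96,
            gsd_m=0.31,
            n_whales=2,
            whale_length_m=(7.0, 9.0),
            seed=seed,
        )
    )
    labeled = assign_labels(tile_scene(scene), scene.whales)
    for t in labeled:
        r0, c0 = t.tile.origin_px
        fracs = [
            inst.mask[r0 : r0 + 32, c0 : c0 + 32].sum() / inst.mask.sum()
            for inst in scene.whales
        ]
        best = max(fracs) if fracs else 0.0
        if best == 0:
            assert t.label == WATER and t.retained
        elif best >= 0.20:
            assert t.label == WHALE and t.retained
        else:
            assert not t.retained


# ------------------------------------------------------------------ datasets
def test_counts_sum_to_retained_total():
    ds = _dataset(5, 12)
    assert ds.counts == {WHALE: 5, WATER: 12}
    assert ds.counts[WHALE] + ds.counts[WATER] == len(ds)


def test_duplicate_tile_ids_rejected():
    t = LabeledTile(_dummy_tile(("x", 0, 0)), WATER, 0.0, True)
    with pytest.raises(ParameterError):
        TileDataset(tiles=[t, t])


# --------------------------------------------------------------- subsampling
def test_subsample_class_counts_and_determinism():
    ds = _dataset(6, 40)
    sub = subsample_class(ds, WATER, 10, seed=4)
    assert sub.counts == {WHALE: 6, WATER: 10}
    sub2 = subsample_class(ds, WATER, 10, seed=4)
    assert [t.tile_id for t in sub.tiles] == [t.tile_id for t in sub2.tiles]
    diff = [
        set(t.tile_id for t in subsample_class(ds, WATER, 10, seed=s).tiles)
        for s in range(20)
    ]
    assert len({frozenset(s) for s in diff}) > 1  # seeds actually vary


def test_subsample_identity_and_overdraw():
    ds = _dataset(3, 8)
    same = subsample_class(ds, WATER, 8, seed=0)
    assert same.counts == ds.counts
    with pytest.raises(ParameterError):
        subsample_class(ds, WATER, 9, seed=0)


# -------------------------------------------------------------------- folds
def test_folds_partition_and_stratify():
    ds = _dataset(20, 123)
    spec = make_folds(ds, n_folds=10, seed=1)
    all_ids = {t.tile_id for t in ds.retained}
    assert set(spec.assignments) == all_ids
    for k in range(10):
        train, test = spec.split(ds, k)
        ids_train = {t.tile_id for t in train.retained}
        ids_test = {t.tile_id for t in test.retained}
        assert ids_train | ids_test == all_ids and not ids_train & ids_test
        assert test.counts[WHALE] == 2
        assert test.counts[WATER] in (12, 13)


def test_fold_of_12306_water_tiles_gives_1230_or_1231_test():
    ds = _dataset(230, 12306)
    spec = make_folds(ds, n_folds=10, seed=0)
    for k in range(10):
        _, test = spec.split(ds, k)
        assert test.counts[WATER] in (1230, 1231)
        assert test.counts[WHALE] == 23


def test_individual_unit_keeps_duplicate_frames_together():
    tiles = []
    for ind in range(5):
        for frame in range(4):
            tiles.append(
                LabeledTile(
                    _dummy_tile((f"i{ind}", frame, 0)), WHALE, 1.0, True, ind
                )
            )
    for i in range(30):
        tiles.append(LabeledTile(_dummy_tile(("o", i, 1)), WATER, 0.0, True))
    ds = TileDataset(tiles=tiles)
    spec = make_folds(ds, n_folds=5, unit="individual", seed=2)
    fold_of = {}
    for t in ds.retained:
        if t.label == WHALE:
            f = spec.assignments[t.tile_id]
            fold_of.setdefault(t.individual_id, set()).add(f)
    assert all(len(folds) == 1 for folds in fold_of.values())


def test_folds_reject_small_classes_and_bad_units():
    ds = _dataset(3, 40)
    with pytest.raises(ParameterError):
        make_folds(ds, n_folds=10)
    with pytest.raises(ParameterError):
        make_folds(ds, n_folds=1)
    with pytest.raises(ParameterError):
        make_folds(_dataset(10, 40), n_folds=5, unit="scene")


# ------------------------------------------------------------ balanced subset
@pytest.mark.parametrize("seed", range(20))
def test_balanced_subset_is_exactly_one_to_one(seed):
    ds = _dataset(7, 50)
    bal = balanced_subset(ds, seed=seed)
    assert bal.counts == {WHALE: 7, WATER: 7}


def test_balanced_subset_identity_and_error():
    ds = _dataset(5, 5)
    assert balanced_subset(ds, seed=0).counts == ds.counts
    with pytest.raises(ParameterError):
        balanced_subset(_dataset(6, 5), seed=0)
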