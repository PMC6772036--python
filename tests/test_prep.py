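"""Raster geometry: down-sampling, pansharpening, band selection, tiling."""

import numpy as np
import pytest

from whaledetect.errors import (
    ConfigurationError,
    DegenerateInputError,
    GridError,
    ParameterError,
)
from whaledetect.prep import (
    Tile,
    TileGrid,
    area_average_resample,
    bilinear_downsample,
    extract_rgb,
    gram_schmidt_pansharpen,
    tile_area_m2,
    tile_scene,
    upscale_tile,
)
from whaledetect.scenes import Scene, SceneParams, block_average, generate_scene


def _plain_scene(pixels, gsd=0.02):
    params = SceneParams(
        width_px=pixels.shape[1], height_px=pixels.shape[0], gsd_m=gsd, n_whales=0
    )
    return Scene("s", pixels, gsd, [], params)


# ---------------------------------------------------------------- downsample
def test_downsample_preserves_constants_and_dimensions():
    scene = _plain_scene(np.full((496, 496, 3), 0.5), gsd=0.02)
    out = bilinear_downsample(scene, 0.31)
    assert out.pixels.shape == (32, 32, 3)  # 496 * 0.02/0.31 = 32
    np.testing.assert_allclose(out.pixels, 0.5, atol=1e-12)
    assert out.gsd_m == 0.31


@pytest.mark.parametrize("seed", range(20))
def test_downsample_mean_intensity_drift_below_1pct(seed):
    scene = generate_scene(
        SceneParams(
            width_px=124, height_px=124, gsd_m=0.05, n_whales=0, sea_state=2, seed=seed
        )
    )
    out = bilinear_downsample(scene, 0.31)
    assert abs(out.pixels.mean() - scene.pixels.mean()) < 0.01 * scene.pixels.mean()


def test_downsample_identity_at_target_gsd():
    scene = generate_scene(
        SceneParams(width_px=64, height_px=64, gsd_m=0.31, n_whales=1, seed=0)
    )
    out = bilinear_downsample(scene, 0.31 + 1e-12)
    np.testing.assert_array_equal(out.pixels, scene.pixels)
    np.testing.assert_array_equal(out.whales[0].mask, scene.whales[0].mask)


def test_downsample_rejects_upsampling_request():
    scene = _plain_scene(np.zeros((64, 64, 3)), gsd=0.31)
    with pytest.raises(ParameterError):
        bilinear_downsample(scene, 0.02)


def test_downsampled_masks_are_fractional_and_conserve_coverage():
    scene = generate_scene(
        SceneParams(
            width_px=620,
            height_px=620,
            gsd_m=0.05,
            n_whales=1,
            whale_length_m=(12.0, 12.0),
            seed=3,
        )
    )
    out = bilinear_downsample(scene, 0.31)
    mask = out.whales[0].mask
    assert mask.dtype.kind == "f"
    assert 0.0 <= mask.min() and mask.max() <= 1.0 + 1e-9
    # Ground-area conservation: sum(mask) * gsd^2 invariant under resampling.
    area_in = scene.whales[0].mask.sum() * scene.gsd_m**2
    area_out = mask.sum() * out.gsd_m**2
    assert area_out == pytest.approx(area_in, rel=1e-6)


def test_area_average_resample_is_exact_on_blocks():
    raster = np.arange(16.0).reshape(4, 4)
    out = area_average_resample(raster, (2, 2))
    np.testing.assert_allclose(out, block_average(raster, 2))


# -------------------------------------------------------------- pansharpening
def test_pansharpen_degenerate_substitution_returns_pan():
    rng = np.random.default_rng(0)
    pan = np.kron(rng.random((8, 8)), np.ones((4, 4)))
    ms = np.stack([block_average(pan, 4)] * 3, axis=2)
    out = gram_schmidt_pansharpen(ms, pan)
    np.testing.assert_allclose(out, np.repeat(pan[:, :, None], 3, axis=2), atol=1e-6)


def test_pansharpen_identity_substitution_returns_upsampled_ms():
    rng = np.random.default_rng(1)
    ms = rng.random((8, 8, 4)) * 0.5 + 0.25
    pan_sim = ms.mean(axis=2)
    pan = np.kron(pan_sim, np.ones((4, 4)))
    out = gram_schmidt_pansharpen(ms, pan)
    expected = np.stack([np.kron(ms[:, :, b], np.ones((4, 4))) for b in range(4)], 2)
    np.testing.assert_allclose(out, expected, atol=1e-9)


@pytest.mark.parametrize("sea_state", range(6))
def test_pansharpen_spectral_consistency_all_sea_states(sea_state):
    """Block-averaging the fused product back to the MS grid reproduces the
    input MS within RMSE < 0.02."""
    scene = generate_scene(
        SceneParams(
            width_px=128,
            height_px=128,
            gsd_m=0.31,
            sea_state=sea_state,
            n_whales=1,
            whale_length_m=(10.0, 12.0),
            seed=40 + sea_state,
            include_ms_pan=True,
        )
    )
    fused = gram_schmidt_pansharpen(scene.ms_bands, scene.pan)
    rmse = np.sqrt(((block_average(fused, 4) - scene.ms_bands) ** 2).mean())
    assert rmse < 0.02


def test_pansharpen_rejects_bad_grids_and_degenerate_pan():
    with pytest.raises(GridError):
        gram_schmidt_pansharpen(np.zeros((8, 8, 3)), np.zeros((30, 32)))
    with pytest.raises(DegenerateInputError):
        gram_schmidt_pansharpen(np.full((8, 8, 3), 0.5), np.random.default_rng(0).random((32, 32)))
    with pytest.raises(ParameterError):
        gram_schmidt_pansharpen(np.zeros((8, 8, 3)), np.zeros((32, 32)), weights=[0, 0, 0])


# ----------------------------------------------------------------- bands
def test_extract_rgb_selects_and_orders_bands():
    ms = np.stack([np.full((4, 4), i / 10) for i in range(8)], axis=2)
    out = extract_rgb(ms, {"red": 4, "green": 2, "blue": 1})
    np.testing.assert_allclose(out[0, 0], [0.4, 0.2, 0.1])


def test_extract_rgb_identity_map():
    rgb = np.random.default_rng(0).random((4, 4, 3))
    out = extract_rgb(rgb, {"red": 0, "green": 1, "blue": 2})
    np.testing.assert_array_equal(out, rgb)


def test_extract_rgb_bounds_and_missing_band():
    ms = np.zeros((4, 4, 8))
    with pytest.raises(ConfigurationError):
        extract_rgb(ms, {"red": 9, "green": 1, "blue": 2})
    with pytest.raises(ConfigurationError):
        extract_rgb(ms, {"red": 1, "green": 2})


# ----------------------------------------------------------------- tiling
def _scene_of_shape(h, w, gsd=0.31, seed=0):
    rng = np.random.default_rng(seed)
    return _plain_scene(rng.random((h, w, 3)), gsd=gsd)


@pytest.mark.parametrize(
    "h, w, tile, stride, expected",
    [
        (64, 96, 32, 32, 6),
        (70, 70, 32, 32, 4),  # 6 trailing rows/cols dropped
        (64, 64, 32, 16, 9),  # floor((64-32)/16)+1 = 3 per axis
    ],
)
def test_tile_counts(h, w, tile, stride, expected):
    scene = _scene_of_shape(h, w)
    grid = TileGrid.for_shape((h, w), tile, stride)
    tiles = tile_scene(scene, grid)
    assert len(tiles) == expected
    assert all(t.pixels.shape == (tile, tile, 3) for t in tiles)


def test_tiles_enumerated_row_major_with_expected_positions():
    scene = _scene_of_shape(64, 96)
    tiles = tile_scene(scene, TileGrid.for_shape((64, 96)))
    assert [t.grid_pos for t in tiles] == [
        (0, 0), (0, 1), (0, 2), (1, 0), (1, 1), (1, 2)
    ]
    assert tiles[4].origin_px == (32, 32)


def test_mosaic_round_trip_bit_exact():
    scene = _scene_of_shape(96, 128, seed=5)
    grid = TileGrid.for_shape((96, 128), 32, 32)
    tiles = tile_scene(scene, grid)
    mosaic = np.zeros_like(scene.pixels)
    for t in tiles:
        r0, c0 = t.origin_px
        mosaic[r0 : r0 + 32, c0 : c0 + 32] = t.pixels
    np.testing.assert_array_equal(mosaic[:96, :128], scene.pixels)


def _brute_force_tiles(H, W, tile, stride, origin=(0, 0)):
    """Sliding-window enumeration oracle."""
    positions = []
    r = origin[0]
    while r + tile <= H:
        c = origin[1]
        while c + tile <= W:
            positions.append((r, c))
            c += stride
        r += stride
    return positions


def test_tile_count_matches_sliding_window_oracle_random_configs():
    rng = np.random.default_rng(123)
    for _ in range(100):
        tile = int(rng.integers(1, 40))
        stride = int(rng.integers(1, tile + 1))
        H = int(rng.integers(tile, 150))
        W = int(rng.integers(tile, 150))
        grid = TileGrid.for_shape((H, W), tile, stride)
        oracle = _brute_force_tiles(H, W, tile, stride)
        assert grid.n_rows * grid.n_cols == len(oracle)
        assert grid.bounds(grid.n_rows - 1, grid.n_cols - 1)[:2][0] == oracle[-1][0]


def test_tiling_rejects_undersized_scene():
    with pytest.raises(GridError):
        TileGrid.for_shape((16, 64), 32)


def test_grid_parameter_validation():
    with pytest.raises(ParameterError):
        TileGrid(tile_px=0)
    with pytest.raises(ParameterError):
        TileGrid(tile_px=32, stride_px=33)


# ----------------------------------------------------------------- area
def test_tile_area_examples():
    assert round(tile_area_m2(32, 0.31), 1) == 98.4
    assert tile_area_m2(1, 1.0) == 1.0
    assert tile_area_m2(32, 0.02) == pytest.approx(0.4096)
    with pytest.raises(ParameterError):
        tile_area_m2(0, 0.31)
    with pytest.raises(ParameterError):
        tile_area_m2(32, 0.0)


# ----------------------------------------------------------------- upscale
def _tile(pixels):
    return Tile(pixels, (0, 0), "s", 0.31, (0, 0))


def test_upscale_constant_and_identity():
    const = _tile(np.full((32, 32, 3), 0.3))
    out = upscale_tile(const, 224)
    assert out.pixels.shape == (224, 224, 3)
    np.testing.assert_allclose(out.pixels, 0.3, atol=1e-9)
    same = upscale_tile(const, 32)
    np.testing.assert_array_equal(same.pixels, const.pixels)


def test_upscale_checker_block_structure():
    checker = np.zeros((32, 32, 3))
    checker[:16, 16:] = 1.0
    checker[16:, :16] = 1.0
    out = upscale_tile(_tile(checker), 224, method="nearest")
    # 224/32 = 7: each original pixel becomes a 7x7 block.
    np.testing.assert_array_equal(
        out.pixels, np.kron(checker.transpose(2, 0, 1), np.ones((7, 7))).transpose(1, 2, 0)
    )


def test_upscale_rejects_shrink_and_unknown_method():
    t = _tile(np.zeros((32, 32, 3)))
    with pytest.raises(ParameterError):
        upscale_tile(t, 16)
    with pytest.raises(ConfigurationError):
        upscale_tile(t, 64, method="sinc")
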