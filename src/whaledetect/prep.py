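"""Raster geometry: GSD-matched down-sampling, Gram-Schmidt pansharpening,
RGB band extraction, tiling, and tile upscaling.

Pixel conventions used throughout: 0-based indices, row-major order, origin
at the top-left, and half-open tile intervals [r*stride, r*stride + tile_px).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import ConfigurationError, DegenerateInputError, GridError, ParameterError
from .scenes import Scene, WhaleInstance, block_average

__all__ = [
    "TileGrid",
    "Tile",
    "bilinear_downsample",
    "gram_schmidt_pansharpen",
    "extract_rgb",
    "tile_scene",
    "tile_area_m2",
    "upscale_tile",
    "area_average_resample",
]


@dataclass(frozen=True)
class TileGrid:
    """A regular tile grid over a raster.

    ``stride_px < tile_px`` yields overlapping tiles; trailing partial strips
    that do not fit a full tile are dropped, never padded.
    """

    tile_px: int = 32
    stride_px: int = 32
    origin: tuple[int, int] = (0, 0)
    n_rows: int = 0
    n_cols: int = 0

    def __post_init__(self) -> None:
        if self.tile_px < 1:
            raise ParameterError("tile_px must be >= 1")
        if not 1 <= self.stride_px <= self.tile_px:
            raise ParameterError("stride_px must satisfy 1 <= stride <= tile_px")
        if min(self.origin) < 0:
            raise ParameterError("origin offsets must be >= 0")

    @classmethod
    def for_shape(
        cls,
        shape_hw: tuple[int, int],
        tile_px: int = 32,
        stride_px: int | None = None,
        origin: tuple[int, int] = (0, 0),
    ) -> "TileGrid":
        """Build the grid covering a raster of shape (H, W).

        n_rows = floor((H - origin_row - tile_px)/stride) + 1, same for cols.
        """
        stride_px = tile_px if stride_px is None else stride_px
        H, W = shape_hw
        grid = cls(tile_px=tile_px, stride_px=stride_px, origin=origin)
        h_avail = H - origin[0] - tile_px
        w_avail = W - origin[1] - tile_px
        if h_avail < 0 or w_avail < 0:
            raise GridError(
                f"raster {H}x{W} smaller than one {tile_px}px tile at origin {origin}"
            )
        return dataclasses.replace(
            grid,
            n_rows=h_avail // stride_px + 1,
            n_cols=w_avail // stride_px + 1,
        )

    def bounds(self, row: int, col: int) -> tuple[int, int, int, int]:
        """Half-open pixel bounds (r0, r1, c0, c1) of tile (row, col)."""
        r0 = self.origin[0] + row * self.stride_px
        c0 = self.origin[1] + col * self.stride_px
        return r0, r0 + self.tile_px, c0, c0 + self.tile_px


@dataclass
class Tile:
    """A tile_px-square crop of a scene."""

    pixels: np.ndarray
    grid_pos: tuple[int, int]
    parent_scene_id: str
    gsd_m: float
    origin_px: tuple[int, int]  # top-left pixel (row, col) in the parent scene

    @property
    def tile_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def tile_id(self) -> str:
        return f"{self.parent_scene_id}_{self.grid_pos[0]}_{self.grid_pos[1]}"


def _area_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Exact 1-D area-overlap weight matrix (n_out x n_in), rows sum to 1.

    Output pixel i covers the input interval [i*r, (i+1)*r) with r = n_in/n_out;
    entry (i, j) is the overlap of that interval with input pixel [j, j+1).
    """
    r = n_in / n_out
    j = np.arange(n_in)
    lo = np.arange(n_out)[:, None] * r
    hi = lo + r
    overlap = np.minimum(hi, j + 1.0) - np.maximum(lo, j)
    W = np.clip(overlap, 0.0, None)
    return W / r


def area_average_resample(raster: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Exact area-weighted average resampling of a 2-D raster.

    Used for masks so that a down-sampled binary mask becomes a fractional
    coverage raster whose total coverage is conserved up to the area ratio.
    """
    H, W = raster.shape
    h, w = out_hw
    Wr = _area_matrix(H, h)
    Wc = _area_matrix(W, w)
    return Wr @ raster.astype(np.float64) @ Wc.T


def bilinear_downsample(scene: Scene, target_gsd_m: float) -> Scene:
    """Down-sample a scene to a coarser GSD with bilinear interpolation.

    Output dimensions are round(dim * src_gsd / target_gsd). Instance masks
    are resampled by exact area-fraction averaging and kept as fractional
    coverage rasters, so downstream whale-fraction bookkeeping stays
    meaningful at the coarse resolution. Requesting a finer GSD is an error
    (use :func:`upscale_tile` for enlargement); requesting the current GSD
    (within 1e-9) is the identity.
    """
    if not target_gsd_m > 0:
        raise ParameterError("target_gsd_m must be > 0")
    if abs(target_gsd_m - scene.gsd_m) <= 1e-9:
        return dataclasses.replace(
            scene,
            pixels=scene.pixels.copy(),
            whales=[dataclasses.replace(w, mask=w.mask.copy()) for w in scene.whales],
        )
    if target_gsd_m < scene.gsd_m:
        raise ParameterError(
            f"target GSD {target_gsd_m} finer than source {scene.gsd_m}: "
            "down-sampling only"
        )

    H, W = scene.shape
    scale = scene.gsd_m / target_gsd_m
    out_h = int(round(H * scale))
    out_w = int(round(W * scale))
    if out_h < 1 or out_w < 1:
        raise ParameterError("target GSD collapses the scene below one pixel")

    pixels = _sk_resize(
        scene.pixels, (out_h, out_w), order=1, anti_aliasing=True, mode="reflect"
    )
    pixels = np.clip(pixels, 0.0, 1.0)

    whales = [
        WhaleInstance(
            instance_id=wi.instance_id,
            mask=area_average_resample(wi.mask.astype(np.float64), (out_h, out_w)),
            length_m=wi.length_m,
            pose_deg=wi.pose_deg,
            individual_id=wi.individual_id,
        )
        for wi in scene.whales
    ]
    return Scene(
        scene_id=scene.scene_id,
        pixels=pixels,
        gsd_m=target_gsd_m,
        whales=whales,
        params=scene.params,
        ms_bands=None,
        pan=None,
    )


def gram_schmidt_pansharpen(
    ms: np.ndarray,
    pan: np.ndarray,
    weights: np.ndarray | list[float] | None = None,
) -> np.ndarray:
    """Fuse a coarse MS stack (h, w, B) with a fine pan band (H, W).

    Procedure (the standard Gram-Schmidt fusion, in its equivalent
    gain/injection form):

    1. simulate a low-resolution pan as the normalized weighted band sum;
    2. treat the simulated pan as the first Gram-Schmidt component and
       compute each band's projection gain g_b = cov(band_b, pan_sim) /
       var(pan_sim);
    3. mean/std-match the true pan to the simulated pan and substitute it —
       the affine match is computed between the *degraded* (block-averaged)
       pan and the simulated pan, so the substituted pan agrees with the
       simulated pan in its coarse-scale statistics and the fused product
       block-averages back to the input MS (spectral consistency);
    4. invert: fused_b = upsample(ms_b) + g_b * (pan_matched -
       upsample(pan_sim)), with block-replicate upsampling.

    Output is clipped to [0, 1]. The pan grid must be an integer multiple of
    the MS grid in both axes; a zero-variance simulated pan is degenerate.
    """
    ms = np.asarray(ms, dtype=np.float64)
    pan = np.asarray(pan, dtype=np.float64)
    if ms.ndim != 3 or pan.ndim != 2:
        raise ParameterError("ms must be (h, w, B) and pan (H, W)")
    h, w, B = ms.shape
    H, W = pan.shape
    if H % h or W % w or H // h != W // w or H // h < 1:
        raise GridError(
            f"pan grid {H}x{W} is not an integer multiple of MS grid {h}x{w}"
        )
    ratio = H // h

    if weights is None:
        weights = np.ones(B)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (B,) or np.any(weights < 0) or weights.sum() <= 0:
        raise ParameterError("weights must be B non-negative values with sum > 0")
    weights = weights / weights.sum()

    pan_sim = np.tensordot(ms, weights, axes=([2], [0]))  # (h, w)
    var_sim = pan_sim.var()
    if var_sim <= 1e-12:
        raise DegenerateInputError("simulated pan has (near-)zero variance")

    centered = ms - ms.mean(axis=(0, 1))
    sim_centered = pan_sim - pan_sim.mean()
    gains = (centered * sim_centered[:, :, None]).mean(axis=(0, 1)) / var_sim  # (B,)

    pan_coarse = block_average(pan, ratio)
    pan_std = pan_coarse.std()
    if pan_std <= 1e-12:
        raise DegenerateInputError("pan band has (near-)zero variance")
    gain = pan_sim.std() / pan_std
    pan_matched = (pan - pan_coarse.mean()) * gain + pan_sim.mean()

    def up(r: np.ndarray) -> np.ndarray:
        return np.kron(r, np.ones((ratio, ratio)))

    detail = pan_matched - up(pan_sim)
    fused = np.stack([up(ms[:, :, b]) for b in range(B)], axis=2)
    fused = fused + gains[None, None, :] * detail[:, :, None]
    return np.clip(fused, 0.0, 1.0)


def extract_rgb(ms: np.ndarray, band_map: dict[str, int]) -> np.ndarray:
    """Select (red, green, blue) bands from an MS stack, in R, G, B order."""
    ms = np.asarray(ms)
    if ms.ndim != 3:
        raise ParameterError("ms must be (H, W, B)")
    B = ms.shape[2]
    try:
        idx = [band_map["red"], band_map["green"], band_map["blue"]]
    except KeyError as missing:
        raise ConfigurationError(f"band_map missing {missing} band") from None
    for i in idx:
        if not 0 <= i < B:
            raise ConfigurationError(f"band index {i} out of range for {B} bands")
    return ms[:, :, idx]


def tile_scene(scene: Scene, grid: TileGrid | None = None) -> list[Tile]:
    """Cut a scene into tiles, enumerated row-major.

    With stride == tile_px the tiles partition the covered region disjointly;
    trailing partial strips are dropped.
    """
    if grid is None or (grid.n_rows == 0 and grid.n_cols == 0):
        base = grid or TileGrid()
        grid = TileGrid.for_shape(
            scene.shape, base.tile_px, base.stride_px, base.origin
        )
    H, W = scene.shape
    if H < grid.tile_px or W < grid.tile_px:
        raise GridError(f"scene {H}x{W} smaller than one {grid.tile_px}px tile")

    tiles: list[Tile] = []
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            r0, r1, c0, c1 = grid.bounds(row, col)
            tiles.append(
                Tile(
                    pixels=scene.pixels[r0:r1, c0:c1].copy(),
                    grid_pos=(row, col),
                    parent_scene_id=scene.scene_id,
                    gsd_m=scene.gsd_m,
                    origin_px=(r0, c0),
                )
            )
    return tiles


def tile_area_m2(tile_px: int, gsd_m: float) -> float:
    """Ground footprint of a square tile: (tile_px * gsd_m)^2 in m^2.

    32 px at 0.31 m/px gives 98.4 m^2 (98.4064 before rounding).
    """
    if tile_px < 1:
        raise ParameterError("tile_px must be >= 1")
    if not gsd_m > 0:
        raise ParameterError("gsd_m must be > 0")
    return (tile_px * gsd_m) ** 2


def upscale_tile(tile: Tile, out_px: int, method: str = "bilinear") -> Tile:
    """Enlarge a tile to out_px square (e.g. 32 -> 224 for a CNN input).

    ``method`` is "bilinear" (default) or "nearest". Requesting out_px equal
    to the current size returns a bit-identical copy; shrinking is an error.
    """
    if out_px < tile.tile_px:
        raise ParameterError(
            f"upscale_tile cannot shrink {tile.tile_px} -> {out_px}"
        )
    if out_px == tile.tile_px:
        return dataclasses.replace(tile, pixels=tile.pixels.copy())
    if method == "bilinear":
        order = 1
    elif method == "nearest":
        order = 0
    else:
        raise ConfigurationError(f"unknown interpolation method {method!r}")
    out = _sk_resize(
        tile.pixels,
        (out_px, out_px),
        order=order,
        anti_aliasing=False,
        mode="edge",
    )
    return dataclasses.replace(tile, pixels=np.clip(out, 0.0, 1.0))
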