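"""Synthetic ocean-scene generator.

Produces seeded, fully labeled ocean scenes at arbitrary ground-sample
distance (GSD) so that the whole detection pipeline — resampling, tiling,
labeling, training, evaluation — is testable without any proprietary aerial
or commercial satellite imagery.

The scene model is deliberately simple and controllable rather than
radiometrically faithful:

* water is a mid-grey blue/green field with low-frequency directional wave
  streaks whose amplitude grows with ``sea_state`` and a Bernoulli whitecap
  speckle whose rate grows with ``sea_state`` (sea_state 0 is flat calm);
* whales are dark, elongated (length:width roughly 5:1) anti-aliased shapes —
  a body ellipse plus a tapered fluke lobe — placed at a uniform random pose,
  darker than the local water by a configurable contrast margin;
* each individual may appear in several "duplicate frames" with jittered
  pose and position, mimicking an aerial survey that photographs the same
  whale from successive camera frames;
* optional distractor objects (bright elongated boats) carry no instance
  record, mimicking non-whale surface objects.

Scenes can optionally carry a simulated multispectral/panchromatic pair: the
pan band is the fine-grid luminance and the MS stack is a 4x coarser
block-average of (blue, green, red, NIR) bands, with NIR modelled as
attenuated luminance. This mirrors a sub-metre sensor whose MS bands are 4x
coarser than pan.

Determinism contract: identical ``SceneParams`` (including ``seed``) yield
bit-identical rasters and masks.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError, SceneGeometryError

__all__ = [
    "SceneParams",
    "WhaleInstance",
    "Scene",
    "generate_scene",
    "generate_paired_survey",
    "MINKE_LIKE_LENGTH_M",
    "LARGE_WHALE_LENGTH_M",
]

#: Default whale length interval for aerial-style scenes, metres ("minke-like").
MINKE_LIKE_LENGTH_M = (7.0, 9.0)
#: Length interval for satellite-style test scenes ("right/humpback-like").
LARGE_WHALE_LENGTH_M = (12.0, 16.0)

# Water base reflectance per channel (R, G, B): dark blue-green.
_WATER_BASE = np.array([0.38, 0.44, 0.50])
# Whitecap probability per pixel and unit of sea state.
_WHITECAP_RATE = 0.004
# Wave-streak amplitude: base + per-sea-state increment.
_WAVE_AMP_BASE = 0.010
_WAVE_AMP_STEP = 0.015
# NIR band model: attenuated luminance (water absorbs NIR strongly).
_NIR_GAIN = 0.55
_NIR_OFFSET = 0.02


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic ocean scene.

    Attributes
    ----------
    width_px, height_px:
        Raster size in pixels; both must be >= 32.
    gsd_m:
        Ground-sample distance in metres per pixel (> 0).
    sea_state:
        Ordinal surface roughness, 0 (flat calm) .. 5 (heavy whitecaps).
    n_whales:
        Number of distinct individuals in the scene.
    whale_length_m:
        Closed sampling interval [min, max] for body length in metres.
    n_duplicate_frames:
        Frames per individual (>= 1); duplicates share ``individual_id`` but
        get an independently jittered pose and position.
    distractors:
        Subset of {"boat", "detritus"}; distractor objects carry no
        instance record.
    seed:
        Master seed; same (params, seed) gives bit-identical output.
    contrast:
        Whale-vs-water intensity offset (subtracted), with mild per-pixel
        jitter. Lower values make harder scenes.
    include_ms_pan:
        Also emit a 4-band MS stack at 4x coarser grid plus a fine pan band.
    """

    width_px: int = 512
    height_px: int = 512
    gsd_m: float = 0.31
    sea_state: int = 1
    n_whales: int = 1
    whale_length_m: tuple[float, float] = MINKE_LIKE_LENGTH_M
    n_duplicate_frames: int = 1
    distractors: frozenset[str] = frozenset()
    seed: int = 0
    contrast: float = 0.15
    include_ms_pan: bool = False

    def __post_init__(self) -> None:
        if self.width_px < 32 or self.height_px < 32:
            raise ParameterError("scene must be at least 32x32 px")
        if not self.gsd_m > 0:
            raise ParameterError(f"gsd_m must be > 0, got {self.gsd_m}")
        if not 0 <= int(self.sea_state) <= 5:
            raise ParameterError("sea_state must be an ordinal in 0..5")
        if self.n_whales < 0:
            raise ParameterError("n_whales must be >= 0")
        lo, hi = self.whale_length_m
        if not (0 < lo <= hi):
            raise ParameterError("whale_length_m must be a positive ordered interval")
        if self.n_duplicate_frames < 1:
            raise ParameterError("n_duplicate_frames must be >= 1")
        unknown = set(self.distractors) - {"boat", "detritus"}
        if unknown:
            raise ParameterError(f"unknown distractors: {sorted(unknown)}")
        if self.include_ms_pan and (self.width_px % 4 or self.height_px % 4):
            raise ParameterError("MS/pan scenes need dimensions divisible by 4")


@dataclass
class WhaleInstance:
    """One whale appearance (one frame of one individual) with its mask.

    ``mask`` is scene-aligned; binary (bool) at native generation, fractional
    coverage (float in [0, 1]) after area-weighted resampling.
    """

    instance_id: int
    mask: np.ndarray
    length_m: float
    pose_deg: float
    individual_id: int

    @property
    def total_pixels(self) -> float:
        """Total (possibly fractional) mask coverage in pixels."""
        return float(self.mask.sum())


@dataclass
class Scene:
    """A labeled ocean raster plus optional MS/pan pair.

    ``pixels`` is H x W x 3 reflectance-like float in [0, 1]; ``ms_bands``
    (if present) is H/4 x W/4 x 4 in band order (blue, green, red, nir) and
    ``pan`` is H x W.
    """

    scene_id: str
    pixels: np.ndarray
    gsd_m: float
    whales: list[WhaleInstance]
    params: SceneParams
    ms_bands: np.ndarray | None = None
    pan: np.ndarray | None = None

    #: Band-name -> index map for ``ms_bands``.
    MS_BAND_MAP = {"blue": 0, "green": 1, "red": 2, "nir": 3}

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


def _shape_coverage(
    shape_hw: tuple[int, int],
    center_rc: tuple[float, float],
    length_px: float,
    pose_deg: float,
    supersample: int = 2,
) -> np.ndarray:
    """Anti-aliased coverage raster of the whale shape.

    The shape is a body ellipse with semi-axes (0.4 L, 0.1 L) whose centre
    sits 0.1 L ahead of the placement centre, plus a fluke lobe ellipse with
    semi-axes (0.1 L, 0.15 L) tangent to the body's rear, so the overall
    major-axis extent is exactly L and the length:width ratio ~5:1.

    Coverage is estimated on a ``supersample``^2 subpixel grid inside the
    shape's bounding window only; returns a full-scene float raster.
    """
    H, W = shape_hw
    bounds = _shape_window_bounds(shape_hw, center_rc, length_px)
    cov_win, (r_lo, r_hi, c_lo, c_hi) = _shape_coverage_window(
        bounds, center_rc, length_px, pose_deg, supersample
    )
    cov = np.zeros((H, W), dtype=np.float64)
    cov[r_lo:r_hi, c_lo:c_hi] = cov_win
    return cov


def _shape_window_bounds(
    shape_hw: tuple[int, int], center_rc: tuple[float, float], length_px: float
) -> tuple[int, int, int, int]:
    H, W = shape_hw
    r0c, c0c = center_rc
    rad = int(np.ceil(length_px / 2)) + 2
    r_lo = max(0, int(np.floor(r0c)) - rad)
    r_hi = min(H, int(np.ceil(r0c)) + rad + 1)
    c_lo = max(0, int(np.floor(c0c)) - rad)
    c_hi = min(W, int(np.ceil(c0c)) + rad + 1)
    return r_lo, r_hi, c_lo, c_hi


def _shape_coverage_window(
    bounds: tuple[int, int, int, int],
    center_rc: tuple[float, float],
    length_px: float,
    pose_deg: float,
    supersample: int = 2,
) -> tuple[np.ndarray, tuple[int, int, int, int]]:
    """Coverage raster restricted to a bounding window; see _shape_coverage."""
    r_lo, r_hi, c_lo, c_hi = bounds
    L = length_px
    theta = np.deg2rad(pose_deg)
    ct, st = np.cos(theta), np.sin(theta)
    r0c, c0c = center_rc

    s = supersample
    offs = (np.arange(s) + 0.5) / s - 0.5
    rr = np.arange(r_lo, r_hi)[:, None] + offs[None, :]  # (h, s)
    cc = np.arange(c_lo, c_hi)[:, None] + offs[None, :]
    # Subpixel sample coordinates relative to the placement centre.
    dr = (rr - r0c).reshape(-1, 1)  # (h*s, 1)
    dc = (cc - c0c).reshape(1, -1)  # (1, w*s)
    # Rotate into whale frame: u along the body axis, v across.
    u = dr * ct + dc * st
    v = -dr * st + dc * ct

    a_body, b_body = 0.4 * L, 0.1 * L
    body = ((u - 0.1 * L) / a_body) ** 2 + (v / b_body) ** 2 <= 1.0
    a_fluke, b_fluke = 0.1 * L, 0.15 * L
    fluke = ((u + 0.4 * L) / a_fluke) ** 2 + (v / b_fluke) ** 2 <= 1.0
    inside = body | fluke

    h = r_hi - r_lo
    w = c_hi - c_lo
    cov_win = inside.reshape(h, s, w, s).mean(axis=(1, 3)).astype(np.float64)
    return cov_win, bounds


def whale_shape_area_px2(length_px: float) -> float:
    """Closed-form area (px^2) of the drawn whale shape: body ellipse
    pi*(0.4L)(0.1L) plus tangent fluke ellipse pi*(0.1L)(0.15L)."""
    return float(np.pi * (0.4 * 0.1 + 0.1 * 0.15) * length_px**2)


#: Grid spacing (m) of the ocean-texture process. Wave streaks and whitecap
#: speckle are physical surface features, so they are generated once on this
#: fixed metric grid and resampled to whatever GSD the sensor uses — a 2 cm
#: aerial scene and a 31 cm satellite scene of the same sea state then show
#: the *same* ocean statistics, which is exactly what lets a model trained on
#: down-sampled aerial imagery transfer to satellite imagery.
_PROCESS_GSD = 0.31


def _water_field(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    """H x W x 3 water background: base colour + directional wave streaks
    (+ whitecap speckle for sea_state > 0), generated in metric units."""
    H, W = params.height_px, params.width_px
    ss = int(params.sea_state)

    scale = params.gsd_m / _PROCESS_GSD
    Hp = max(8, int(np.ceil(H * scale)))
    Wp = max(8, int(np.ceil(W * scale)))
    native = abs(params.gsd_m - _PROCESS_GSD) <= 1e-9

    noise = rng.standard_normal((Hp, Wp))
    # Anisotropic smoothing -> horizontal wave streaks (correlation lengths
    # ~0.6 m across, ~2.5-5.6 m along, lengthening with sea state).
    waves = ndimage.gaussian_filter(noise, sigma=(2.0, 8.0 + 2.0 * ss))
    sd = waves.std()
    if sd > 0:
        waves = waves / sd
    amp = _WAVE_AMP_BASE + _WAVE_AMP_STEP * ss
    deviation = (amp * waves).astype(np.float32)

    cap_alpha = cap_value = None
    if ss > 0:
        cap_mask = rng.random((Hp, Wp)) < _WHITECAP_RATE * ss
        # Dilate caps slightly so they read as multi-pixel foam patches.
        cap_mask = ndimage.binary_dilation(cap_mask, iterations=1)
        cap_val = rng.uniform(0.92, 1.0, size=(Hp, Wp)).astype(np.float32)
        cap_alpha = cap_mask.astype(np.float32)
        cap_value = cap_val * cap_alpha

    if not native:
        from skimage.transform import resize as _resize

        deviation = _resize(deviation, (H, W), order=1, anti_aliasing=False)
        deviation = deviation.astype(np.float32)
        if cap_alpha is not None:
            cap_alpha = _resize(cap_alpha, (H, W), order=1, anti_aliasing=False)
            cap_alpha = cap_alpha.astype(np.float32)
            cap_value = _resize(cap_value, (H, W), order=1, anti_aliasing=False)
            cap_value = cap_value.astype(np.float32)

    # Per-scene-pixel sensor jitter (a sensor property, not an ocean one).
    shading = (rng.standard_normal((H, W)) * 0.004).astype(np.float32)
    base = (
        _WATER_BASE.astype(np.float32)[None, None, :]
        + (deviation + shading)[:, :, None]
    )
    if cap_alpha is not None:
        base = base * (1.0 - cap_alpha[:, :, None]) + cap_value[:, :, None]
    return np.clip(base, 0.0, 1.0)


def _place_center(
    params: SceneParams, length_px: float, rng: np.random.Generator
) -> tuple[float, float]:
    H, W = params.height_px, params.width_px
    margin = length_px / 2 + 2
    if 2 * margin >= H or 2 * margin >= W:
        raise SceneGeometryError(
            f"whale of {length_px:.0f} px does not fit a {H}x{W} px scene"
        )
    r = rng.uniform(margin, H - margin)
    c = rng.uniform(margin, W - margin)
    return r, c


def _draw_boat(
    pixels: np.ndarray, params: SceneParams, rng: np.random.Generator
) -> None:
    """Bright elongated distractor; no instance record."""
    length_m = rng.uniform(15.0, 25.0)
    length_px = length_m / params.gsd_m
    H, W = params.height_px, params.width_px
    if length_px / 2 + 2 >= min(H, W) / 2:
        length_px = min(H, W) / 3.0
    r, c = _place_center(params, length_px, rng)
    pose = rng.uniform(0.0, 360.0)
    cov = _shape_coverage((H, W), (r, c), length_px, pose)
    pixels += 0.35 * cov[:, :, None]
    np.clip(pixels, 0.0, 1.0, out=pixels)


def generate_scene(params: SceneParams) -> Scene:
    """Generate one seeded scene with whale instances and masks.

    Emits exactly ``n_whales * n_duplicate_frames`` :class:`WhaleInstance`
    records; duplicate frames of one individual share ``individual_id`` and
    differ in pose/position. Raises :class:`SceneGeometryError` when a
    sampled whale cannot fit inside the scene.
    """
    rng = np.random.default_rng(params.seed)
    pixels = _water_field(params, rng)

    lo, hi = params.whale_length_m
    max_len_px = hi / params.gsd_m
    H, W = params.height_px, params.width_px
    if params.n_whales > 0 and max_len_px / 2 + 2 >= min(H, W) / 2:
        raise SceneGeometryError(
            f"whale_length_m up to {hi} m is {max_len_px:.0f} px at "
            f"{params.gsd_m} m/px and cannot fit a {H}x{W} px scene"
        )

    whales: list[WhaleInstance] = []
    inst = 0
    for ind in range(params.n_whales):
        length_m = float(rng.uniform(lo, hi))
        for _ in range(params.n_duplicate_frames):
            length_px = length_m / params.gsd_m
            r, c = _place_center(params, length_px, rng)
            pose = float(rng.uniform(0.0, 360.0))
            bounds = _shape_window_bounds((H, W), (r, c), length_px)
            cov_win, (r_lo, r_hi, c_lo, c_hi) = _shape_coverage_window(
                bounds, (r, c), length_px, pose
            )
            jitter = 1.0 + 0.1 * rng.standard_normal(cov_win.shape)
            pixels[r_lo:r_hi, c_lo:c_hi] -= (
                params.contrast * cov_win * jitter
            )[:, :, None]
            mask = np.zeros((H, W), dtype=bool)
            mask[r_lo:r_hi, c_lo:c_hi] = cov_win >= 0.5
            whales.append(
                WhaleInstance(
                    instance_id=inst,
                    mask=mask,
                    length_m=length_m,
                    pose_deg=pose,
                    individual_id=ind,
                )
            )
            inst += 1
    np.clip(pixels, 0.0, 1.0, out=pixels)

    if "boat" in params.distractors:
        _draw_boat(pixels, params, rng)
    if "detritus" in params.distractors:
        # Small dark clutter speckle patches.
        clutter = rng.random((H, W)) < 0.0005
        clutter = ndimage.binary_dilation(clutter, iterations=2)
        pixels = np.where(clutter[:, :, None], pixels - 0.08, pixels)
        np.clip(pixels, 0.0, 1.0, out=pixels)

    ms_bands = pan = None
    if params.include_ms_pan:
        lum = pixels.mean(axis=2)
        pan = lum.copy()
        nir = np.clip(_NIR_GAIN * lum + _NIR_OFFSET, 0.0, 1.0)
        fine = np.stack(
            [pixels[:, :, 2], pixels[:, :, 1], pixels[:, :, 0], nir], axis=2
        )
        ms_bands = block_average(fine, 4)

    return Scene(
        scene_id=f"scene{params.seed:010d}",
        pixels=pixels,
        gsd_m=params.gsd_m,
        whales=whales,
        params=params,
        ms_bands=ms_bands,
        pan=pan,
    )


def block_average(raster: np.ndarray, factor: int) -> np.ndarray:
    """Average ``factor`` x ``factor`` blocks of a (H, W) or (H, W, B) raster."""
    H, W = raster.shape[:2]
    if H % factor or W % factor:
        raise ParameterError("raster dimensions must be divisible by the factor")
    if raster.ndim == 2:
        return raster.reshape(H // factor, factor, W // factor, factor).mean(
            axis=(1, 3)
        )
    B = raster.shape[2]
    return raster.reshape(H // factor, factor, W // factor, factor, B).mean(
        axis=(1, 3)
    )


def generate_paired_survey(
    aerial: SceneParams,
    satellite: SceneParams,
    n_aerial: int = 10,
    n_satellite: int = 4,
) -> tuple[list[Scene], list[Scene]]:
    """Generate an aerial training collection and a satellite test collection.

    The aerial GSD must be strictly finer than the satellite GSD (train on
    down-sampled fine imagery, test at native coarse resolution). Per-scene
    seeds are spawned deterministically from each collection's master seed.
    """
    if not aerial.gsd_m < satellite.gsd_m:
        raise ParameterError(
            f"aerial GSD ({aerial.gsd_m}) must be finer than satellite GSD "
            f"({satellite.gsd_m})"
        )

    def _collection(base: SceneParams, n: int) -> list[Scene]:
        child_seeds = np.random.SeedSequence(base.seed).generate_state(n) % (2**31)
        return [
            generate_scene(dataclasses.replace(base, seed=int(s)))
            for s in child_seeds
        ]

    return _collection(aerial, n_aerial), _collection(satellite, n_satellite)
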