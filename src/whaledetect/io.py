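"""Raster and manifest I/O.

Scenes are written as 8-bit PNG (or GeoTIFF via tifffile when requested)
plus a JSON sidecar carrying {gsd_m, seed, params}; instance masks go to a
single-channel 16-bit label raster (0 = water, k = instance k); a manifest
CSV lists scene -> instances. Tiles export as PNGs named
{scene}_{row}_{col}.png with a manifest CSV. Rasters are reflectance-like
floats in [0, 1] in memory and quantised to 8 bits on export.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .datasets import TileDataset
from .errors import ParameterError
from .scenes import Scene, SceneParams, WhaleInstance

__all__ = [
    "save_scene",
    "load_scene",
    "save_tiles",
    "load_tile_pixels",
    "write_manifest",
]


def _params_to_json(params: SceneParams) -> dict:
    d = dataclasses.asdict(params)
    d["distractors"] = sorted(d["distractors"])
    d["whale_length_m"] = list(d["whale_length_m"])
    return d


def _params_from_json(d: dict) -> SceneParams:
    d = dict(d)
    d["distractors"] = frozenset(d["distractors"])
    d["whale_length_m"] = tuple(d["whale_length_m"])
    return SceneParams(**d)


def save_scene(scene: Scene, out_dir: str | Path, fmt: str = "png") -> Path:
    """Write pixels, label mask, and JSON sidecar; returns the raster path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    u8 = np.clip(np.round(scene.pixels * 255), 0, 255).astype(np.uint8)
    if fmt == "png":
        raster = out_dir / f"{scene.scene_id}.png"
        iio.imwrite(raster, u8)
    elif fmt == "gtiff":
        raster = out_dir / f"{scene.scene_id}.tif"
        tifffile.imwrite(
            raster,
            u8,
            resolution=(1.0 / scene.gsd_m, 1.0 / scene.gsd_m),
            metadata={"gsd_m": scene.gsd_m},
        )
    else:
        raise ParameterError(f"unknown raster format {fmt!r}")

    # Label raster: 0 = water, k = instance k (binary masks only; fractional
    # masks are a runtime representation and are not exported).
    labels = np.zeros(scene.shape, dtype=np.uint16)
    for wi in scene.whales:
        mask = wi.mask >= 0.5 if wi.mask.dtype != bool else wi.mask
        labels[mask] = wi.instance_id + 1
    iio.imwrite(out_dir / f"{scene.scene_id}_mask.png", labels)

    sidecar = {
        "scene_id": scene.scene_id,
        "gsd_m": scene.gsd_m,
        "seed": scene.params.seed,
        "params": _params_to_json(scene.params),
        "instances": [
            {
                "instance_id": wi.instance_id,
                "individual_id": wi.individual_id,
                "length_m": wi.length_m,
                "pose_deg": wi.pose_deg,
            }
            for wi in scene.whales
        ],
    }
    (out_dir / f"{scene.scene_id}.json").write_text(json.dumps(sidecar, indent=2))
    return raster


def load_scene(out_dir: str | Path, scene_id: str) -> Scene:
    """Load a PNG/GeoTIFF scene written by :func:`save_scene`."""
    out_dir = Path(out_dir)
    sidecar = json.loads((out_dir / f"{scene_id}.json").read_text())
    png = out_dir / f"{scene_id}.png"
    tif = out_dir / f"{scene_id}.tif"
    if png.exists():
        u8 = iio.imread(png)
    elif tif.exists():
        u8 = tifffile.imread(tif)
    else:
        raise FileNotFoundError(f"no raster for {scene_id} in {out_dir}")
    pixels = u8.astype(np.float64) / 255.0

    labels = iio.imread(out_dir / f"{scene_id}_mask.png")
    whales = [
        WhaleInstance(
            instance_id=inst["instance_id"],
            mask=labels == inst["instance_id"] + 1,
            length_m=inst["length_m"],
            pose_deg=inst["pose_deg"],
            individual_id=inst["individual_id"],
        )
        for inst in sidecar["instances"]
    ]
    return Scene(
        scene_id=scene_id,
        pixels=pixels,
        gsd_m=sidecar["gsd_m"],
        whales=whales,
        params=_params_from_json(sidecar["params"]),
    )


def save_tiles(dataset: TileDataset, out_dir: str | Path) -> pd.DataFrame:
    """Export tile PNGs plus a manifest CSV; returns the manifest frame."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = dataset.to_manifest()
    paths = []
    for t in dataset.tiles:
        name = f"{t.tile.parent_scene_id}_{t.tile.grid_pos[0]}_{t.tile.grid_pos[1]}.png"
        u8 = np.clip(np.round(t.tile.pixels * 255), 0, 255).astype(np.uint8)
        iio.imwrite(out_dir / name, u8)
        paths.append(name)
    manifest["path"] = paths
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_tile_pixels(tile_dir: str | Path, name: str) -> np.ndarray:
    return iio.imread(Path(tile_dir) / name).astype(np.float64) / 255.0


def write_manifest(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
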