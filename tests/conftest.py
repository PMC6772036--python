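"""Shared fixtures: all data is generated programmatically at test time.

The two session-scoped experiment fixtures run the shipped quickstart recipe
(easy and hard conditions) exactly once; several test modules read from them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from whaledetect.pipeline import ExperimentConfig, quickstart_config, run_experiment
from whaledetect.scenes import SceneParams, generate_scene


@pytest.fixture(scope="session")
def easy_result():
    """Full end-to-end quickstart run, easy condition (contrast 0.15, calm)."""
    return run_experiment(quickstart_config(seed=1))


@pytest.fixture(scope="session")
def hard_result():
    """Full end-to-end quickstart run, hard condition (contrast 0.05, sea 3)."""
    return run_experiment(quickstart_config(seed=1, hard=True))


def mini_config(seed: int = 0) -> ExperimentConfig:
    """A few-second configuration for plumbing/determinism tests: coarse
    aerial GSD (8 cm) so the down-sampling factor stays small."""
    base = quickstart_config(seed=seed)
    aerial = dataclasses.replace(
        base.aerial, width_px=744, height_px=744, gsd_m=0.08
    )
    satellite = dataclasses.replace(
        base.satellite, width_px=160, height_px=160, n_whales=1
    )
    train = dataclasses.replace(base.train, n_epochs=6)
    return dataclasses.replace(
        base,
        aerial=aerial,
        satellite=satellite,
        n_aerial=6,
        n_satellite=2,
        train=train,
        seed=seed,
    )


@pytest.fixture()
def mini_cfg() -> ExperimentConfig:
    return mini_config(seed=3)


@pytest.fixture(scope="session")
def sat_scene():
    """One satellite-style labeled scene with an MS/pan pair."""
    return generate_scene(
        SceneParams(
            width_px=320,
            height_px=320,
            gsd_m=0.31,
            sea_state=2,
            n_whales=2,
            whale_length_m=(12.0, 16.0),
            seed=11,
            include_ms_pan=True,
        )
    )


def tiny_training_scenes(
    n_scenes: int = 7,
    size_px: int = 256,
    contrast: float = 0.2,
    sea_state: int = 0,
    seed: int = 0,
):
    """Native-resolution scenes for fast classifier tests (~64 tiles each)."""
    seeds = np.random.SeedSequence(seed).generate_state(n_scenes) % (2**31)
    return [
        generate_scene(
            SceneParams(
                width_px=size_px,
                height_px=size_px,
                gsd_m=0.31,
                sea_state=sea_state,
                n_whales=2,
                whale_length_m=(9.0, 12.0),
                seed=int(s),
                contrast=contrast,
            )
        )
        for s in seeds
    ]
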