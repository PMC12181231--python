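"""Shared fixtures: small synthetic scenes and a desk-scale trained cascade."""

from __future__ import annotations

import numpy as np
import pytest

import dropcascade as dc

#: Desk-scale training conditions used by the learned-segmentation checks:
#: 12 training scenes + 4 held-out scenes of 128x128 px with 6 droplets of
#: radius ~10 px, balanced phase mix, cut into 64x64 tiles (48 tiles/stage).
SCENE_HW = 128
TILE_HW = (64, 64)
GRID = (1, 1)
N_TRAIN_SCENES = 12
N_TEST_SCENES = 4
DROPLETS_PER_SCENE = 6

DESK_SPEC = dc.UNetSpec(n_encoders=2, base_filters=8, learning_rate=2e-3,
                        batch_size=8, n_epochs=60, seed=0)


def make_scene_spec(**overrides) -> dc.SceneSpec:
    base = dict(image_height_px=SCENE_HW, image_width_px=SCENE_HW,
                droplets_per_frame=DROPLETS_PER_SCENE, droplet_radius_px=10.0,
                radius_jitter=0.1)
    base.update(overrides)
    return dc.SceneSpec(**base)


def make_scenes(n: int, seed0: int):
    """Rendered scenes with a balanced ACC/vaterite/calcite phase mix."""
    spec = make_scene_spec()
    scenes = []
    for i in range(n):
        rng = np.random.default_rng(1000 + seed0 + i)
        phases = [(dc.ACC, dc.VATERITE, dc.CALCITE)[rng.integers(0, 3)]
                  for _ in range(spec.droplets_per_frame)]
        scenes.append(dc.generate_scene(spec, phases, seed=seed0 + i))
    return scenes


def tiles_of(img, is_mask):
    ts = dc.cut_and_resize(img, GRID, TILE_HW, is_mask=is_mask)
    return [t.image for t in ts.tiles]


@pytest.fixture(scope="session")
def training_scenes():
    return make_scenes(N_TRAIN_SCENES, seed0=0)


@pytest.fixture(scope="session")
def heldout_scenes():
    return make_scenes(N_TEST_SCENES, seed0=500)


@pytest.fixture(scope="session")
def trained_cascade(training_scenes):
    """Three desk-scale U-Nets trained on synthetic tiles (stage 2/3 inputs
    are overlays with the ground-truth droplet masks)."""
    pairs = {"droplet": [], "vaterite": [], "calcite": []}
    for rgb, dm, vm, cm, _truth in training_scenes:
        ov = dc.overlay(rgb, dm)
        for a, b in zip(tiles_of(rgb, False), tiles_of(dm, True)):
            pairs["droplet"].append((a, b))
        for a, b in zip(tiles_of(ov, False), tiles_of(vm, True)):
            pairs["vaterite"].append((a, b))
        for a, b in zip(tiles_of(ov, False), tiles_of(cm, True)):
            pairs["calcite"].append((a, b))
    cfg = dc.TrainConfig(seed=0)
    models = tuple(
        dc.train_model(dc.build_unet(DESK_SPEC), pairs[stage], cfg)
        for stage in ("droplet", "vaterite", "calcite")
    )
    return models
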