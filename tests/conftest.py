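"""Shared fixtures: synthetic scenes and trained classifiers are expensive,
so they are built once per session and reused read-only."""

from __future__ import annotations

import numpy as np
import pytest

from earsilk import plant_segmentation as seg
from earsilk import synthetic_scenes as syn
from earsilk.config import PipelineConfig


@pytest.fixture(scope="session")
def default_scene():
    """One deterministic plant-day: 12 side views + top view + ground truth."""
    spec = syn.PlantSpec(leaf_plane_azimuth=30.0, rng_seed=1)
    views, truth = syn.generate_plant_scene(spec)
    return spec, views, truth


@pytest.fixture(scope="session")
def mean_side_image(default_scene):
    _, views, _ = default_scene
    return seg.mean_image(views.side_views)


@pytest.fixture(scope="session")
def top_classifier():
    """Decision tree trained on labelled pixels from a contrasting scene."""
    rng = np.random.default_rng(2024)
    spec = syn.PlantSpec(leaf_plane_azimuth=135.0, rng_seed=77)
    views, truth = syn.generate_plant_scene(spec)
    top, tm = views.top_view, truth.top_mask
    plant_px = top[tm]
    bg_px = top[~tm]
    n = 3000
    X = np.concatenate([
        plant_px[rng.choice(len(plant_px), n, replace=False)],
        bg_px[rng.choice(len(bg_px), n, replace=False)],
    ]).astype(float)
    y = np.concatenate([np.ones(n, dtype=int), np.zeros(n, dtype=int)])
    return seg.train_top_classifier(X, y)


@pytest.fixture(scope="session")
def ear_series():
    spec = syn.SilkScenarioSpec(rate_max=800.0, duration=4.0, n_days=8, rng_seed=3)
    images, truth = syn.generate_ear_series(spec)
    return spec, images, truth


@pytest.fixture()
def config():
    return PipelineConfig()
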