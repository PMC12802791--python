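import dataclasses

import numpy as np
import pytest

from thromboseg import SceneConfig, ThresholdConfig


@pytest.fixture
def noise_free_config():
    """Deterministic rendering: no noise, no blur, no distractor, no text."""
    return SceneConfig(
        noise_sd=0.0,
        blur_sigma_px=0.0,
        distractor_enabled=False,
        annotation_enabled=False,
    )


@pytest.fixture
def smoke_scene_config():
    """A small, fast scene configuration for pipeline smoke tests."""
    return SceneConfig(
        image_size=64,
        vessel_diameter_px=12.0,
        marker_radius_px=1.0,
        cluster_x_spread_px=3.0,
        annotation_band_px=6,
        noise_sd=1.0,
        blur_sigma_px=0.3,
    )


@pytest.fixture
def smoke_thresholds():
    return ThresholdConfig(annotation_band_px=8, target_size=32)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def replace(cfg, **kw):
    return dataclasses.replace(cfg, **kw)
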