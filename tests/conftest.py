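import time

import numpy as np
import pytest

from nucleotrace.pipeline import run_pipeline, train_model
from nucleotrace.synthetic import SceneConfig, sample_scene


@pytest.fixture(scope="session")
def default_model():
    """Classifier trained once on the standard calibration scene."""
    return train_model()


@pytest.fixture(scope="session")
def default_run(default_model):
    """Full pipeline once on the default desk-scale scene, with wall time."""
    cfg = SceneConfig(rng_seed=42)
    cells, truth = sample_scene(cfg)
    t0 = time.perf_counter()
    res = run_pipeline(cells, cfg, default_model)
    elapsed = time.perf_counter() - t0
    return cfg, cells, truth, res, elapsed


@pytest.fixture(scope="session")
def small_scene():
    """A modest scene reused by tests that only need plausible data."""
    cfg = SceneConfig(n_cells=30, n_frames=10, frame_shape=(192, 192),
                      rng_seed=11)
    cells, truth = sample_scene(cfg)
    return cfg, cells, truth


def make_detection(frame, row, col, label=1, area=150, h_mean=1000.0,
                   h_min=100.0, h_max=3000.0, h_sd=400.0, pi_mean=10.0):
    """Hand-built detection for tracking/classification fixtures."""
    from nucleotrace.types import Channel, NucleusDetection

    return NucleusDetection(
        label=label, frame_index=frame, channel=Channel.HOECHST,
        centroid=(float(row), float(col)), area_px=area, hoechst_mean=h_mean,
        hoechst_min=h_min, hoechst_max=h_max, hoechst_sd=h_sd,
        pi_mean=pi_mean)


@pytest.fixture
def detection_factory():
    return make_detection


def rng(seed=0):
    return np.random.default_rng(seed)
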