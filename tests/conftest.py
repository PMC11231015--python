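"""Shared fixtures: coarse fixture geometry and one smoke-trained model.

Heavy artifacts (the smoke benchmark training run and the end-to-end
pipeline run) are session-scoped so every test file shares them.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from sonocomplete.completion_model import (
    PRESETS,
    make_sphere_benchmark,
    train,
)
from sonocomplete.fixtures import VertebraParams, make_spine
from sonocomplete.pipeline import RunConfig, run_pipeline
from sonocomplete.us_occlusion import OcclusionConfig

# Coarser grids than the library defaults keep the suite fast; the geometry
# and physics under test are resolution-independent.
FAST_PARAMS = VertebraParams(resolution=2.5)
FAST_GRID = (24, 24, 60.0)


@pytest.fixture(scope="session")
def vertebra_params() -> VertebraParams:
    return FAST_PARAMS


@pytest.fixture(scope="session")
def spine():
    """Straight-ish five-level fixture spine with its landmark table."""
    return make_spine(params=FAST_PARAMS, lordosis_deg=10.0, seed=3)


@pytest.fixture(scope="session")
def straight_spine():
    return make_spine(params=FAST_PARAMS, lordosis_deg=0.0, seed=3)


@pytest.fixture(scope="session")
def sphere_pairs():
    """The 200-pair sphere-with-cap-removed smoke benchmark dataset."""
    return make_sphere_benchmark(200, PRESETS["smoke"], seed=0)


@pytest.fixture(scope="session")
def smoke_model(sphere_pairs):
    """Smoke-preset model trained for 30 epochs on the sphere benchmark."""
    model, history = train(sphere_pairs, PRESETS["smoke"])
    return model, history


def fast_run_config(out_dir: str, seed: int = 0) -> RunConfig:
    """Small end-to-end configuration (desk scale, one CPU)."""
    return RunConfig(
        out_dir=out_dir,
        seed=seed,
        n_spines=3,
        vertebra_resolution=3.0,
        jitter_mm=0.2,
        occlusion=OcclusionConfig(
            n_curvatures=2,
            grid=FAST_GRID,
            n_points=128,
            n_gt=128,
        ),
        preset="smoke",
        epochs=4,
        # at 128-point density the 1%-diagonal threshold is below the mean
        # sampling spacing; use ~10% of the normalized radius instead
        fscore_threshold=0.1,
        poisson_depth=5,
    )


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full pipeline run: fixtures → … → evaluate → reconstruct."""
    out = tmp_path_factory.mktemp("run") / "smoke"
    cfg = dataclasses.replace(fast_run_config(str(out)), batch_size=4)
    run_dir = run_pipeline(cfg, stages=None)
    return run_dir, cfg


@pytest.fixture(scope="session")
def pipeline_rerun(pipeline_run, tmp_path_factory):
    """Second pipeline run with the identical config and seed."""
    _, cfg = pipeline_run
    out = tmp_path_factory.mktemp("rerun") / "smoke"
    cfg2 = dataclasses.replace(cfg, out_dir=str(out))
    return run_pipeline(cfg2, stages=None)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240515)
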