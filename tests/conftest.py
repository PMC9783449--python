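"""Shared fixtures: small, fast geometry and synthetic runs.

Unit tests use a 32-channel array and coarse grids so each module can be
exercised in seconds; the end-to-end acceptance tests build the full-size
64-channel configuration themselves.
"""

from __future__ import annotations

import numpy as np
import pytest

from iedmap.config import PipelineConfig
from iedmap.containers import ConductorModel, SourceGrid
from iedmap.forward import compute_leadfield, make_sensor_array
from iedmap.synthetic_meg import focal_spike_wave_scenario, simulate_recording


@pytest.fixture(scope="session")
def conductor():
    return ConductorModel(center=np.zeros(3), radius=0.09)


@pytest.fixture(scope="session")
def sensors32():
    return make_sensor_array(32, 0.09, 0.02)


@pytest.fixture(scope="session")
def sensors64():
    return make_sensor_array(64, 0.09, 0.02)


@pytest.fixture(scope="session")
def grid10(conductor):
    """Coarse 10 mm grid for fast beamformer tests."""
    return SourceGrid.regular(conductor, 10.0)


@pytest.fixture(scope="session")
def leadfield10(grid10, conductor, sensors32):
    return compute_leadfield(grid10, conductor, sensors32)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-cost pipeline configuration for unit tests."""
    return PipelineConfig(hmm_grid_mm=8.0, ekm_grid_mm=10.0, n_restarts=2, max_iter=100)


@pytest.fixture(scope="session")
def spike_run(sensors32, conductor):
    """40 s focal spike-wave run on the small array, with ground truth."""
    scenario = focal_spike_wave_scenario(seed=7, duration=40.0)
    rec, gt = simulate_recording(scenario, sensors32, conductor)
    return rec, gt, scenario


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
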