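import datetime as dt

import numpy as np
import pandas as pd
import pytest

import opencamscr as oc
from opencamscr.capture_data import DetectorArray, Detector, SessionSpec


@pytest.fixture(scope="session")
def study_array() -> DetectorArray:
    """The survey's 55-site checkerboard design with paired cameras."""
    return oc.make_grid_design(10, 11, 2_700.0, cameras_per_site=2)


@pytest.fixture(scope="session")
def study_mask(study_array):
    return oc.build_mask(study_array, 18_000.0, 1_000.0)


@pytest.fixture(scope="session")
def small_spec() -> SessionSpec:
    periods = [(dt.date(2009 + y, 9, 15), dt.date(2009 + y, 10, 25)) for y in range(3)]
    return SessionSpec(periods)


@pytest.fixture(scope="session")
def sim_history(study_array, study_mask):
    """A reduced-scale simulated robust-design dataset with ground truth."""
    params = oc.SimulationParams(n_primary=5, n_secondary=50, N_initial=38, seed=3)
    traj = oc.simulate_population(params, study_mask)
    history = oc.simulate_detections(traj, study_array, params)
    return params, traj, history


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    from opencamscr.cli import generate_fixtures

    out = tmp_path_factory.mktemp("fixtures")
    return out, generate_fixtures(out, seed=11)


@pytest.fixture
def tiny_array() -> DetectorArray:
    return DetectorArray(
        [
            Detector("c1a", "s1", 0.0, 0.0),
            Detector("c1b", "s1", 0.0, 0.0),
            Detector("c2a", "s2", 3_000.0, 0.0),
        ]
    )
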