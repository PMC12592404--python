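import dataclasses

import numpy as np
import pytest

from magest.datamodel import Modality, Session, SessionDesign, Task, default_config
from magest.pipeline import default_observer_params
from magest.simulate import CohortSpec, simulate_cohort, simulate_participant


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_cfg(cfg):
    """Default sets but light trial counts (36/36 temporal, 24/24 spatial)."""
    designs = {
        Task.TEMPORAL: SessionDesign(Task.TEMPORAL, 36, 36),
        Task.SPATIAL: SessionDesign(Task.SPATIAL, 24, 24),
    }
    return dataclasses.replace(cfg, session_designs=designs)


@pytest.fixture(scope="session")
def temporal_participant(cfg):
    """One calibrated seg_audio observer, full default temporal design."""
    params = default_observer_params(cfg, Task.TEMPORAL, "seg_audio", seed=11)
    return simulate_participant(params, cfg, Task.TEMPORAL, participant_id="P01")


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """Five-participant temporal cohort with motor noise, light design."""
    base = default_observer_params(small_cfg, Task.TEMPORAL, "seg_audio", seed=5)
    base = dataclasses.replace(base, motor_sd=15.0)
    spec = CohortSpec(n_participants=5, base_params=base, master_seed=5)
    return simulate_cohort(spec, small_cfg, Task.TEMPORAL)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
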