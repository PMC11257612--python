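"""Shared fixtures: published parameters and (expensive) synthetic datasets.

Session-scoped fixtures cache the calibrated track generator and the three
synthetic experiments so the unit tests and the acceptance tests share one
copy of each.
"""

import numpy as np
import pytest

from chemoinfo.models import Environment
from chemoinfo.params import load_published
from chemoinfo.synthetic import (
    PopulationSpec,
    StepProtocol,
    calibrate_swim_generator,
    generate_noise_dataset,
    generate_step_response_dataset,
    generate_track_dataset,
)

SEED = 0


@pytest.fixture(scope="session")
def published():
    """(swim, kin, env) population medians at c0 = 1 uM."""
    return load_published(1.0)


@pytest.fixture(scope="session")
def published_generation():
    """Same, with the generator's kinase phenotype (tau_1 > 0)."""
    return load_published(1.0, generation=True)


@pytest.fixture(scope="session")
def calibrated_swim(published):
    swim, _, _ = published
    return calibrate_swim_generator(swim.sigma_v2, swim.tau_v, swim)


@pytest.fixture(scope="session")
def track_dataset(calibrated_swim, published):
    _, kin, env = published
    pop = PopulationSpec(swim=calibrated_swim, kin=kin, n_cells=500,
                         measurement_noise_sd=0.0)
    return generate_track_dataset(
        pop, Environment(c0=1.0, g=0.0, k_D=env.k_D), 60.0, 0.05, seed=SEED)


@pytest.fixture(scope="session")
def step_dataset(calibrated_swim, published_generation):
    _, kin, env = published_generation
    pop = PopulationSpec(swim=calibrated_swim, kin=kin, n_cells=30)
    proto = StepProtocol.for_background(1.0)
    return generate_step_response_dataset(pop, env, proto, seed=SEED), proto


@pytest.fixture(scope="session")
def noise_dataset(calibrated_swim, published):
    _, kin, env = published
    pop = PopulationSpec(swim=calibrated_swim, kin=kin, n_cells=50)
    return generate_noise_dataset(pop, env, seed=SEED)
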