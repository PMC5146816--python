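import logging

import numpy as np
import pytest

from survpower import SimulationConfig, simulate_dataset

# per-replicate convergence warnings are expected noise in power studies
logging.getLogger("survpower.power").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def basic_sim():
    """A moderately censored single-SNP design used across tests."""
    return SimulationConfig(
        n_subjects=200,
        maf=0.3,
        shape_a=1.0,
        baseline_scale_d0=0.1,
        beta_snp=0.4,
        scenario=2,
        end_of_study_Z=5.0,
        censor_scale=4.0,
        seed=42,
    )


@pytest.fixture
def basic_dataset(basic_sim):
    return simulate_dataset(basic_sim)


@pytest.fixture
def treatment_sim():
    """Design with a treatment arm and interaction, scenario 4."""
    return SimulationConfig(
        n_subjects=300,
        maf=0.3,
        shape_a=1.0,
        baseline_scale_d0=0.1,
        beta_snp=0.4,
        beta_trt=0.3,
        beta_int=0.2,
        treat_prob=0.5,
        scenario=4,
        end_of_study_Z=5.0,
        recruit_end_R=2.0,
        censor_scale=4.0,
        seed=7,
    )


@pytest.fixture
def treatment_dataset(treatment_sim):
    return simulate_dataset(treatment_sim)
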