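from pathlib import Path

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from obesim.economics import run_ce_analysis, value_trace
from obesim.markov_engine import run_arm
from obesim.synthetic_data import SyntheticSpec, generate_parameter_set
from obesim.trajectories import build_arm_trajectory

FIXTURES_DIR = Path(__file__).resolve().parent.parent / "fixtures"


@pytest.fixture(scope="session")
def step1_params():
    return generate_parameter_set(SyntheticSpec(seed=0, profile="step1_like"))


@pytest.fixture(scope="session")
def null_params():
    return generate_parameter_set(SyntheticSpec(seed=0, profile="null"))


@pytest.fixture(scope="session")
def treatment_trajectory(step1_params):
    return build_arm_trajectory(step1_params, "treatment")


@pytest.fixture(scope="session")
def comparator_trajectory(step1_params):
    return build_arm_trajectory(step1_params, "comparator")


@pytest.fixture(scope="session")
def treatment_trace(step1_params, treatment_trajectory):
    return run_arm(step1_params, treatment_trajectory)


@pytest.fixture(scope="session")
def comparator_trace(step1_params, comparator_trajectory):
    return run_arm(step1_params, comparator_trajectory)


@pytest.fixture(scope="session")
def base_ce_result(step1_params):
    return run_ce_analysis(step1_params)


@pytest.fixture(scope="session")
def arm_economics(step1_params, treatment_trace, comparator_trace):
    return (value_trace(treatment_trace, step1_params),
            value_trace(comparator_trace, step1_params))
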