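import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the shared oracles module

from cytonet import build_day_matrix, control_matrix, make_cohort
from cytonet.simulate import SimulationConfig


@pytest.fixture(scope="session")
def cohort31():
    """Study-scale cohort: 31 septic patients, 13 controls, seed 7."""
    return make_cohort(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def cohort200():
    """Large cohort for structure-recovery checks."""
    return make_cohort(SimulationConfig(n_patients=200, seed=7))


@pytest.fixture(scope="session")
def day1(cohort31):
    return build_day_matrix(cohort31, 1)


@pytest.fixture(scope="session")
def controls(cohort31):
    return control_matrix(cohort31)
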