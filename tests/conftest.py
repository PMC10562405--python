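import numpy as np
import pandas as pd
import pytest

from maskddm.design import balanced_design, build_design
from maskddm.models import DDMParams, GROUP_MEANS
from maskddm.simulate import simulate_participant


@pytest.fixture(scope="session")
def group_mean_params() -> DDMParams:
    return GROUP_MEANS


@pytest.fixture(scope="session")
def session_design() -> pd.DataFrame:
    return build_design(seed=11)


@pytest.fixture(scope="session")
def small_participant(group_mean_params, session_design) -> pd.DataFrame:
    """One synthetic participant at the group-mean parameters (608 trials)."""
    return simulate_participant(group_mean_params, session_design, seed=202)


@pytest.fixture(scope="session")
def medium_participant(group_mean_params) -> pd.DataFrame:
    """A large balanced dataset (500 trials/cell) for distributional checks."""
    design = balanced_design(500, seed=5)
    return simulate_participant(group_mean_params, design, seed=77)
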