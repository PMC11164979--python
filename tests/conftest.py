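import numpy as np
import pandas as pd
import pytest

from agroemf.config import RunConfig
from agroemf.synthetic import (
    CVModel,
    SimulationParams,
    generate_design,
    generate_function_panel,
)


@pytest.fixture(scope="session")
def design10() -> pd.DataFrame:
    return generate_design(10, seed=42)


@pytest.fixture(scope="session")
def quiet_params() -> SimulationParams:
    """Zero-noise parameters: deterministic panel, exact group means."""
    return SimulationParams(
        years=[2016, 2017, 2018],
        noise_sd={},
        cv_model=CVModel(0.0, 0.0, 0.0),
        trait_coupling=False,
        seed=7,
    )


@pytest.fixture(scope="session")
def quiet_panel(design10, quiet_params) -> pd.DataFrame:
    return generate_function_panel(design10, quiet_params)


@pytest.fixture(scope="session")
def default_run():
    """One shared full pipeline run (seed 3) for pipeline-level tests."""
    from agroemf.pipeline import run_pipeline

    return run_pipeline(RunConfig(seed=3))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
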