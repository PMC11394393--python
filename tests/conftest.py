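import numpy as np
import pytest

from hemoinfer import (
    Cohort,
    EKFConfig,
    LOConfig,
    PatientParams,
    PopulationModel,
    SimSettings,
    nominal_patient,
)


@pytest.fixture(scope="session")
def pop() -> PopulationModel:
    """Default stand-in population."""
    return PopulationModel.from_cv()


@pytest.fixture(scope="session")
def nominal(pop) -> PatientParams:
    return nominal_patient(pop)


@pytest.fixture(scope="session")
def lo_cfg(nominal) -> LOConfig:
    return LOConfig(params_nominal=nominal)


@pytest.fixture(scope="session")
def ekf_cfg(pop, nominal) -> EKFConfig:
    return EKFConfig(params_nominal=nominal, q_theta=pop.q_theta, q_v=0.0)


@pytest.fixture(scope="session")
def nominal_cohort(nominal) -> Cohort:
    return Cohort.from_params([nominal])


@pytest.fixture(scope="session")
def short_settings() -> SimSettings:
    """Reduced horizon for unit tests that do not need 8-hour runs."""
    return SimSettings(t_max=240.0)
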