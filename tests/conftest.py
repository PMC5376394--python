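import numpy as np
import pytest

from cipropbpk.dataset import Subject
from cipropbpk.pbpk_core import (PBPKParameters, UnboundConversionTable,
                                 default_parameters, repeated_doses)
from cipropbpk.physiology import Individual, PhysiologyTable, scale_physiology


@pytest.fixture(scope="session")
def default_table():
    return PhysiologyTable.default()


@pytest.fixture(scope="session")
def ep_table():
    return UnboundConversionTable.default()


@pytest.fixture(scope="session")
def typical_individual():
    """Study-mean ICU patient: 77 kg male, CRCL 82 ml/min."""
    return Individual(id="typical", weight=77.0, sex="male", crcl=82.0)


@pytest.fixture(scope="session")
def typical_organs(typical_individual, default_table):
    return scale_physiology(typical_individual, default_table)


@pytest.fixture(scope="session")
def estimate_params() -> PBPKParameters:
    return default_parameters("estimate")


@pytest.fixture(scope="session")
def truth_theta(estimate_params) -> dict:
    theta = {f"kp_{t}": v for t, v in estimate_params.kp.items()}
    theta["cl_nr"] = estimate_params.cl_nr
    theta["f_secretion"] = estimate_params.f_secretion
    return theta


@pytest.fixture(scope="session")
def rich_noise_free_subjects(truth_theta):
    """Four subjects with dense noise-free sampling; exact population data."""
    from cipropbpk.population_fit import PBPKLikelihood

    covariates = [(77.0, "male", 82.0), (60.0, "female", 45.0),
                  (95.0, "male", 130.0), (70.0, "female", 100.0)]
    obs_t = np.array([0.5, 1.0, 1.25, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 11.5,
                      12.5, 13.0, 14.0, 18.0, 23.5, 25.0, 30.0, 35.5])
    doses = repeated_doses(400.0, 12.0, 1.0, 4)
    skeleton = [Subject(Individual(f"I{i}", w, s, c), doses, obs_t,
                        np.zeros(obs_t.size))
                for i, (w, s, c) in enumerate(covariates)]
    lik = PBPKLikelihood(skeleton)
    return [Subject(s.individual, doses, obs_t,
                    lik.predict_log(truth_theta, (0.0, 0.0), i))
            for i, s in enumerate(skeleton)]
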