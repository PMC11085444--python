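"""Shared fixtures: trained workflow models and synthetic datasets.

Heavy objects (rendered cohorts, fitted models) are session-scoped; every
test that needs a trained cascade reuses the same seed-1 study.
"""

import numpy as np
import pytest
from hypothesis import settings

import honeyscreen as hs
from honeyscreen.preprocess import assemble_matrix
from honeyscreen.workflow import train_workflow

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

LABEL = {"none": "N", "tadalafil": "T", "sildenafil": "S"}


@pytest.fixture(scope="session")
def acq():
    return hs.AcquisitionModel()


@pytest.fixture(scope="session")
def acq_nf(acq):
    return acq.noise_free()


@pytest.fixture(scope="session")
def training(acq):
    cohort = hs.training_cohort(acq, seed=1)
    matrix = assemble_matrix(cohort.spectra)
    labels = [LABEL[m["adulterant"]] for m in matrix.meta]
    return cohort, matrix, labels


@pytest.fixture(scope="session")
def calib_tadalafil(acq):
    cal = hs.make_calibration_set("tadalafil", acq=acq, seed=7)
    return assemble_matrix([s for s, _ in cal]), np.array([c for _, c in cal])


@pytest.fixture(scope="session")
def calib_sildenafil(acq):
    cal = hs.make_calibration_set("sildenafil", acq=acq, seed=8)
    return assemble_matrix([s for s, _ in cal]), np.array([c for _, c in cal])


@pytest.fixture(scope="session")
def models(training, calib_tadalafil, calib_sildenafil):
    _, matrix, labels = training
    return train_workflow(matrix, labels, calib_tadalafil, calib_sildenafil)


@pytest.fixture(scope="session")
def models_noise_free(acq_nf):
    """Cascade trained entirely on noise-free spectra (exact-recovery tests)."""
    cohort = hs.training_cohort(acq_nf, seed=2)
    matrix = assemble_matrix(cohort.spectra)
    labels = [LABEL[m["adulterant"]] for m in matrix.meta]
    cal_t = hs.make_calibration_set("tadalafil", acq=acq_nf, seed=3)
    cal_s = hs.make_calibration_set("sildenafil", acq=acq_nf, seed=4)
    return train_workflow(
        matrix,
        labels,
        (assemble_matrix([s for s, _ in cal_t]), np.array([c for _, c in cal_t])),
        (assemble_matrix([s for s, _ in cal_s]), np.array([c for _, c in cal_s])),
    )


@pytest.fixture
def base_confusers():
    """A fixed mid-range honey matrix for single-sample recipes."""
    return {
        "sugar": 1.0,
        "water": 0.2,
        "chloroform": 0.03,
        "5-HMF": 0.07,
        "formic acid": 0.03,
        "acetic acid": 0.08,
        "2,3-butanediol": 0.08,
    }
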