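"""Shared fixtures.

Expensive objects (ODE trajectories, fitted patients, cohorts) are session
scoped so the cost is paid once for the whole run.
"""

from __future__ import annotations

import numpy as np
import pytest

from tacpredict.cohort import CohortConfig, generate_cohort, sample_patient, simulate_measurements
from tacpredict.constants import DEFAULT_CONSTANTS
from tacpredict.errors import ErrorModelSpec
from tacpredict.estimation import FitOptions, PatientModelContext, fit_map
from tacpredict.parameters import FitParameters
from tacpredict.pbpk import build_model, simulate
from tacpredict.physiology import PatientPhysiology, study_dosing


@pytest.fixture(scope="session")
def constants():
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def median_physiology():
    """Population-median patient (weights, volumes, GFR at reported medians)."""
    return PatientPhysiology(
        weight_kg=76.5,
        height_cm=176.5,
        gfr_ml_min_1p73m2=70.0,
        volumes_l={"kidneys": 0.36, "spleen": 0.18, "liver": 1.80, "tumour1": 0.03, "tumour2": 0.03},
        total_tumour_volume_l=0.11,
        tumour_liver_fraction={"diagnostic": 0.0244, "therapeutic": 0.0824},
    )


@pytest.fixture(scope="session")
def median_dosing():
    return study_dosing()


@pytest.fixture(scope="session")
def median_model(median_physiology, constants):
    return build_model(median_physiology, constants, FitParameters.default())


@pytest.fixture(scope="session")
def median_trajectory(median_model, median_dosing):
    """Dense high-accuracy simulation of the full study timeline."""
    return simulate(median_model, median_dosing, t_end=40000.0, dense=True)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_patients=3, seed=7)


@pytest.fixture(scope="session")
def noisefree_patient(small_config):
    """One virtual patient with noise-free measurements (truth attached)."""
    p = sample_patient(small_config, 0)
    p.measurements = simulate_measurements(
        p, small_config, seed=99, b_true={k: 0.0 for k in small_config.b_true}
    )
    return p


@pytest.fixture(scope="session")
def noisefree_recovery_fit(noisefree_patient, constants):
    """Cold all-data fit of the noise-free patient (no prior)."""
    ctx = PatientModelContext(noisefree_patient.physiology, constants, noisefree_patient.dosing)
    spec = ErrorModelSpec.uniform("data_based", "four_b", 0.2)
    result = fit_map(
        noisefree_patient.measurements, spec, None, FitParameters.default(), ctx, FitOptions()
    )
    return result


@pytest.fixture(scope="session")
def tiny_cohort(constants):
    """Two-patient noisy cohort for workflow plumbing tests."""
    from tacpredict.workflow import Cohort

    cfg = CohortConfig(n_patients=2, seed=3)
    return Cohort.from_virtual(generate_cohort(cfg), constants), cfg


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
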