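import dataclasses

import numpy as np
import pytest

import hepecv as h
from hepecv.config import ExperimentConfig


@pytest.fixture(scope="session")
def default_specs():
    """The three calibrated cohort specs, keyed by group label."""
    return {s.group_label: s for s in h.default_cohort_specs()}


@pytest.fixture()
def control_subject():
    """A deterministic control animal at the group means."""
    return h.SubjectGroundTruth(
        subject_id="control-000",
        group_label="control",
        true_ve=0.18,
        native_t1_liver=593.3,
        native_t1_blood=1600.0,
        haematocrit=0.45,
        sirius_red=0.1,
        portal_pressure=9.0,
    )


@pytest.fixture(scope="session")
def tiny_config():
    """A fast 2-subjects-per-group experiment configuration."""
    specs = tuple(
        dataclasses.replace(s, n_subjects=2) for s in h.default_cohort_specs()
    )
    return ExperimentConfig(cohorts=specs, master_seed=11)


@pytest.fixture(scope="session")
def lossless_config(tiny_config):
    """Noiseless, instantly-equilibrating variant: ECV must equal true_ve."""
    return dataclasses.replace(
        tiny_config, snr=np.inf, kinetics=h.instant_equilibration_params()
    )
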