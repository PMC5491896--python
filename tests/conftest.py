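from __future__ import annotations

import pytest

from stopp_pip.rules import default_rule_library
from stopp_pip.synth import ArmParams, GeneratorConfig, generate_study, paperlike_config
from stopp_pip.terminology import default_codesets


@pytest.fixture(scope="session")
def codesets():
    return default_codesets()


@pytest.fixture(scope="session")
def library():
    return default_rule_library()


def stress_arm(**overrides) -> ArmParams:
    """An arm with every corruption mechanism switched on, for tests
    that need the messy paths exercised rather than realistic rates."""
    base = dict(
        frac_age_ge65=0.4,
        ghost_active_frac=0.3,
        coded_med_frac=0.7,
        no_current_meds_frac=0.3,
        problem_list_usage=0.25,
        missing_gender_frac=0.05,
        missing_dob_frac=0.05,
        invalid_dob_frac=0.03,
        concordance_drug_frac=0.1,
        scope_prevalence=0.2,
        pip_prevalence=0.3,
    )
    base.update(overrides)
    return ArmParams(**base)


def stress_config(seed: int, patients: int = 200, clinics_per_arm: int = 1) -> GeneratorConfig:
    return GeneratorConfig(
        seed=seed,
        n_clinics_per_arm=clinics_per_arm,
        patients_per_clinic=patients,
        control=stress_arm(),
        intervention=stress_arm(scope_prevalence=0.15, pip_prevalence=0.2),
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest paper-like study shared by read-only tests."""
    return generate_study(paperlike_config(seed=7, patients_per_clinic=400))
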