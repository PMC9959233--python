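import numpy as np
import pytest

import nlmetest as nt
from nlmetest.engine import CohortData, FitOptions


@pytest.fixture(scope="session")
def clean_config():
    return nt.GeneratorConfig(n_subjects=60)


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    """Small correctly-specified cohort with 1:1 allocation."""
    cohort = nt.generate_natural_history(clean_config, seed=101)
    return nt.randomize_allocation(cohort, seed=102)


@pytest.fixture(scope="session")
def clean_data(clean_cohort):
    return CohortData.from_cohort(clean_cohort)


@pytest.fixture(scope="session")
def effect_cohort():
    """150-subject clean cohort with a strong (8-point) offset effect."""
    cfg = nt.GeneratorConfig(n_subjects=150)
    cohort = nt.generate_natural_history(cfg, seed=201)
    cohort = nt.randomize_allocation(cohort, seed=202)
    scen = nt.EffectScenario(drug_form="offset", typical_effect=8.0)
    return nt.inject_treatment_effect(cohort, scen, seed=203)


@pytest.fixture(scope="session")
def effect_data(effect_cohort):
    return CohortData.from_cohort(effect_cohort)


@pytest.fixture(scope="session")
def fast_options():
    """Battery-grade fit options (FO route for the one nonlinear drug
    model, slightly relaxed f-tolerance)."""
    return FitOptions(route="fo", ftol=1e-7)
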