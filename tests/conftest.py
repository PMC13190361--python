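import numpy as np
import pandas as pd
import pytest

from fact8d.design import DCEDesign
from fact8d.estimation import ConditionalLogitQALY
from fact8d.simulate import default_true_parameters, simulate_cohort


@pytest.fixture(scope="session")
def design():
    """One built design shared across the suite (seeded, modest search)."""
    return DCEDesign.build(seed=0, n_candidates=30)


@pytest.fixture(scope="session")
def choice_sets(design):
    return design.choice_sets


@pytest.fixture(scope="session")
def truth():
    return default_true_parameters()


@pytest.fixture(scope="session")
def cohort_small(choice_sets, truth):
    """300 engaged respondents: enough signal for qualitative checks."""
    return simulate_cohort(choice_sets, n_respondents=300, params=truth, seed=11)


@pytest.fixture(scope="session")
def cohort_medium(choice_sets, truth):
    """2000 respondents, the study's analysis scale."""
    return simulate_cohort(choice_sets, n_respondents=2000, params=truth, seed=12)


@pytest.fixture(scope="session")
def fit_small(cohort_small):
    return ConditionalLogitQALY().fit(cohort_small.choices)


@pytest.fixture(scope="session")
def fit_medium(cohort_medium):
    return ConditionalLogitQALY().fit(cohort_medium.choices)


@pytest.fixture()
def tiny_choices(choice_sets):
    """Three choice sets from one simulated respondent, for oracle checks."""
    cohort = simulate_cohort(choice_sets, n_respondents=1, seed=3)
    sets = cohort.choices["set_id"].unique()[:3]
    return cohort.choices[cohort.choices["set_id"].isin(sets)].reset_index(drop=True)
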