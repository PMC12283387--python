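"""Shared fixtures: one moderate synthetic dataset reused across tests."""

import pytest

from weightgx import phenotyping, simulate


@pytest.fixture(scope="session")
def sim_config():
    return simulate.config_from_dict(
        {
            "seed": 11,
            "studies": [
                {"study_id": "S1", "ancestry_mix": {"EUR": 1.0}, "n_individuals": 1200},
                {
                    "study_id": "S2",
                    "ancestry_mix": {"EUR": 0.5, "AFR": 0.3, "AMR": 0.2},
                    "n_individuals": 1200,
                },
            ],
        }
    )


@pytest.fixture(scope="session")
def tables(sim_config):
    return simulate.simulate_study(sim_config)


@pytest.fixture(scope="session")
def glp1_cohort(tables):
    cohort, attrition = phenotyping.build_cohort(tables, "glp1")
    return cohort, attrition


@pytest.fixture(scope="session")
def bs_cohort(tables):
    cohort, attrition = phenotyping.build_cohort(tables, "bs")
    return cohort, attrition
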