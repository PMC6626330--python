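"""Shared fixtures: one small synthetic panel reused across module tests."""

import pytest

import highutil as hu


@pytest.fixture(scope="session")
def small_config() -> hu.GeneratorConfig:
    return hu.GeneratorConfig(n_members=3000, seed=7)


@pytest.fixture(scope="session")
def small_data(small_config) -> hu.SyntheticData:
    return hu.simulate(small_config)


@pytest.fixture(scope="session")
def cohort_2012(small_data):
    return hu.build_cohort(small_data.members, small_data.claims,
                           small_data.mapping, 2012)


@pytest.fixture(scope="session")
def design_2012(cohort_2012):
    return hu.build_design_matrix(cohort_2012)


@pytest.fixture(scope="session")
def linear_2012(design_2012):
    return hu.fit_linear(design_2012)
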