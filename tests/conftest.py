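import pytest

from brcaclass.simulate import (
    CohortSpec,
    discussion_cases_fixture,
    generate_cohort,
    generate_resource_tables,
)


@pytest.fixture(scope="session")
def default_spec():
    return CohortSpec(seed=11)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    """Default synthetic cohort (121 records) with its ground-truth ledger."""
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def default_tables(default_spec, default_cohort):
    records, ground_truth = default_cohort
    return generate_resource_tables(default_spec, records, ground_truth)


@pytest.fixture()
def discussion_cases():
    return discussion_cases_fixture()
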