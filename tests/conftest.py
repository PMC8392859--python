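import pytest

from riverwq import pivot_to_matrix
from riverwq.synthetic import make_fixture_suite


@pytest.fixture(scope="session")
def fixture_suite():
    """Named synthetic datasets with ground truth (seeded)."""
    return make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def tiny(fixture_suite):
    records, truth = fixture_suite["tiny"]
    return pivot_to_matrix(records, site_tiers=truth.tier_of_site), truth


@pytest.fixture(scope="session")
def separated_tiers(fixture_suite):
    records, truth = fixture_suite["separated-tiers"]
    return pivot_to_matrix(records, site_tiers=truth.tier_of_site), truth


@pytest.fixture(scope="session")
def trended(fixture_suite):
    records, truth = fixture_suite["trended"]
    return pivot_to_matrix(records, site_tiers=truth.tier_of_site), truth


@pytest.fixture(scope="session")
def rank3_noiseless(fixture_suite):
    records, truth = fixture_suite["rank3-noiseless"]
    return pivot_to_matrix(records, site_tiers=truth.tier_of_site), truth
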