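import pytest

from jointnet import table1_fixture
from jointnet.maxent import standard_constraints, sequential_fit


@pytest.fixture(scope="session")
def fixture_tally():
    tally, _ = table1_fixture()
    return tally


@pytest.fixture(scope="session")
def fixture_class_counts():
    _, counts = table1_fixture()
    return counts


@pytest.fixture(scope="session")
def fitted_trajectory_compat(fixture_tally):
    """Full four-constraint fit with the table-compatible f4 centering."""
    return sequential_fit(
        fixture_tally, standard_constraints("paper-table-1-compat"), df=9, level=0.99
    )


@pytest.fixture(scope="session")
def fitted_trajectory_model(fixture_tally):
    """Full four-constraint fit with model-based f4 centering."""
    return sequential_fit(
        fixture_tally, standard_constraints("model"), df=9, level=0.99
    )
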