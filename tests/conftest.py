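import logging

import pytest

from fatracer.assimilation import diet_baseline
from fatracer.tables import fixture_from_tables


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    # keep expected-warning chatter (APE clamps etc.) out of test output
    logging.getLogger("fatracer").setLevel(logging.ERROR)
    yield


@pytest.fixture(scope="session")
def table_fixture():
    return fixture_from_tables()


@pytest.fixture(scope="session")
def baseline(table_fixture):
    return diet_baseline(table_fixture.diet, table_fixture.in_situ)
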