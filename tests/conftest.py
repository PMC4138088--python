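import logging

import pytest

from coatscreen import build_catalog, load_fixture
from coatscreen.catalog import SubunitIdentity, System
from coatscreen.report import run_pipeline

logging.getLogger("coatscreen").setLevel(logging.ERROR)
logging.getLogger("coatscreen.screen").setLevel(logging.ERROR)


def ident(system: str, complex_: str, subunit: str) -> SubunitIdentity:
    return SubunitIdentity(System(system), complex_, subunit)


@pytest.fixture(scope="session")
def arabidopsis():
    return load_fixture("arabidopsis")


@pytest.fixture(scope="session")
def rice():
    return load_fixture("rice")


@pytest.fixture(scope="session")
def arabidopsis_catalog(arabidopsis):
    queries, _, _ = arabidopsis
    return build_catalog(queries)


@pytest.fixture(scope="session")
def arabidopsis_report(arabidopsis):
    return run_pipeline(*arabidopsis)


@pytest.fixture(scope="session")
def rice_report(rice):
    return run_pipeline(*rice)
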