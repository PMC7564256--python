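import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from ferroleate import (
    composed_reactions,
    standard_reactions,
    standard_recipes,
    standard_registry,
    standard_thermo_table,
)


@pytest.fixture(scope="session")
def registry():
    return standard_registry()


@pytest.fixture(scope="session")
def reactions():
    return standard_reactions()


@pytest.fixture(scope="session")
def recipes():
    return standard_recipes()


@pytest.fixture(scope="session")
def composed():
    return composed_reactions()


@pytest.fixture(scope="session")
def thermo():
    return standard_thermo_table()
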