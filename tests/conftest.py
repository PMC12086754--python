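import pytest

from pedrsp.analysis import Pipeline
from pedrsp.proton_model import ProtonBeamContext
from pedrsp.reference_data import (
    adult70,
    builtin_spectrum,
    gammex,
    load_cross_sections,
    load_elements,
)


@pytest.fixture(scope="session")
def xs():
    return load_cross_sections()


@pytest.fixture(scope="session")
def elements():
    return load_elements()


@pytest.fixture(scope="session")
def ctx(elements):
    return ProtonBeamContext(elements=elements)


@pytest.fixture(scope="session")
def spectrum_140(xs):
    return builtin_spectrum("140kVp")


@pytest.fixture(scope="session")
def adult_db():
    return adult70()


@pytest.fixture(scope="session")
def gammex_db():
    return gammex()


@pytest.fixture(scope="session")
def pipeline():
    """One shared analysis pipeline (Schneider fit, curves, DECT model)."""
    return Pipeline()
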