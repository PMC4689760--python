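import numpy as np
import pytest

from sterolflux.isotopes import ion_composition, parse_formula


@pytest.fixture(scope="session")
def lanosterol():
    return parse_formula("C30H50O")


@pytest.fixture(scope="session")
def cholesterol():
    return parse_formula("C27H46O")


@pytest.fixture(scope="session")
def lanosterol_ion(lanosterol):
    """Monitored dehydrated protonated ion composition (C30H49)."""
    return ion_composition(lanosterol, "[M+H-H2O]+")


@pytest.fixture
def rng():
    return np.random.default_rng(20151223)
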