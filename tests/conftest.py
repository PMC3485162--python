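import numpy as np
import pytest

from umpcr.panel import load_maize_panel, load_reference_oligos
from umpcr.puritytyping import default_reference_profiles


@pytest.fixture(scope="session")
def maize_panel():
    """The bundled five-locus U-panel with adapters attached."""
    return load_maize_panel()


@pytest.fixture(scope="session")
def reference_oligos():
    """All published oligos with their reported Tm values."""
    return load_reference_oligos()


@pytest.fixture(scope="session")
def refs(maize_panel):
    return default_reference_profiles(maize_panel.locus_names)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120815)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
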