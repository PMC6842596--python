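import numpy as np
import pytest

from unwindability import helix_builder as hb
from unwindability import sbm_forcefield as ff


@pytest.fixture(scope="session")
def rna_hexamer():
    return hb.build_duplex("GCGCGC", "RNA")


@pytest.fixture(scope="session")
def dna_hexamer():
    return hb.build_duplex("GCGCGC", "DNA")


@pytest.fixture(scope="session")
def rna_topology(rna_hexamer):
    return ff.build_topology(rna_hexamer)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
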