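import numpy as np
import pytest

from readerscope.ptm_chemistry import h4_tail_proteoforms, isobaric_groups


@pytest.fixture(scope="session")
def h4_forms():
    """The 16 acetyl configurations of the H4 4-17 tail peptide."""
    return h4_tail_proteoforms()


@pytest.fixture(scope="session")
def h4_groups(h4_forms):
    """Isobaric mass groups of the 16 acetyl configurations (1/4/6/4/1)."""
    return isobaric_groups(h4_forms)


@pytest.fixture
def rng():
    return np.random.default_rng(20090901)
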