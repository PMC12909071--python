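import numpy as np
import pytest

# the quadruplex in the ARPC2 5'UTR, written 5'->3' (dye labels omitted)
ARPC2 = "UGGGGGCUGGGCGGGGACCGGGU"

# stem-loop control RNA (no quadruplex)
STEM_LOOP = "UCUCUCUCUCGAGAGAGAGA"

# designed-peptide panel with the experimentally observed verdicts
PANEL_VERDICTS = [
    ("(RQ)10", False),
    ("(RQ)15", True),
    ("(RQ)20", True),
    ("(RGG)13", True),
    ("(RP)15", True),
    ("(RP)20", True),
    ("(RE)20", False),
    ("R30", True),
]


@pytest.fixture
def arpc2():
    return ARPC2


@pytest.fixture
def stem_loop():
    return STEM_LOOP


@pytest.fixture
def panel_verdicts():
    return list(PANEL_VERDICTS)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
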