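import numpy as np
import pytest

from odira import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture
def small_genome():
    """5 kb genome with the worked-example IIR: TGGC / 61 nt / GCCA."""
    return simulate.build_genome(1, 5000, [(4, 61, 2000, "TGGC")])


@pytest.fixture
def two_iir_genome():
    """8 kb genome with a CJ-side and a TJ-side IIR for amplicon products."""
    return simulate.build_genome(3, 8000, [(5, 50, 2000), (6, 70, 6000)])
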