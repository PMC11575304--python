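import numpy as np
import pytest

from metacrispr.io_core import CRISPR1, CRISPR3, Read
from metacrispr.simulate import SimConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def crispr3():
    return CRISPR3


@pytest.fixture
def crispr1():
    return CRISPR1


@pytest.fixture
def noiseless_config():
    """No errors, no dimers, no contaminants, no read competition."""
    return SimConfig(
        per_base_error_rate=0.0,
        dimer_reads_expected=0.0,
        contaminant_rate=0.0,
        background_mass=0.0,
        pcr_dispersion_sigma=0.0,
        read_depth=1000,
    )


def random_read(rng, length, qmin=2, qmax=41, read_id="r"):
    seq = "".join(rng.choice(list("ACGT"), size=length))
    qual = tuple(int(q) for q in rng.integers(qmin, qmax + 1, size=length))
    return Read(id=read_id, seq=seq, qual=qual)
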