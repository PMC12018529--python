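import numpy as np
import pytest

from seqepi import degrees as dg


@pytest.fixture(scope="session")
def study_distributions():
    """The four mean-10 degree families used throughout the numerical
    illustrations: constant, Poisson, geometric, power law with cutoff."""
    return {
        "constant": dg.constant(10),
        "poisson": dg.poisson(10),
        "geometric": dg.geometric(0.1),
        "powerlaw": dg.powerlaw_cutoff(1.0, 36.6472),
    }


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
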