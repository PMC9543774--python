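import numpy as np
import pytest

from lssgrad.core import GradientProgram, LSSParameters


@pytest.fixture
def protein_params():
    """A strongly retained protein-like compound (on-off retention)."""
    return LSSParameters(S=150.0, log_k0=60.0)


@pytest.fixture
def protein_gradient():
    """Narrow-window gradient typical of intact-protein work."""
    return GradientProgram(Ci=0.25, Cf=0.45, tg=10.0, t0=0.1, tD=0.2)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
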