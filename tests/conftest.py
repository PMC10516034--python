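import numpy as np
import pytest

from tricorr import (
    LagWindow,
    compute_triple_correlation,
    generate_feedforward_raster,
)


@pytest.fixture(scope="session")
def window54() -> LagWindow:
    """The worked example's lag window: spatial -5..5, temporal -4..4."""
    return LagWindow(S=5, T=4)


@pytest.fixture(scope="session")
def ff_raster():
    """16 isolated three-spike feedforward motifs (48 spikes), fixed seed."""
    return generate_feedforward_raster(n_motifs=16, rng=np.random.default_rng(42))


@pytest.fixture(scope="session")
def ff_tensor(ff_raster, window54):
    return compute_triple_correlation(ff_raster, window54)
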