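"""Shared fixtures: reference tissues, protocols, and rng streams."""

import numpy as np
import pytest

from dwires import NoiseModel, Tissue
from dwires.protocols import PROTOCOLS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def baseline():
    """Reference tumour microstructure used throughout the change analyses."""
    return Tissue(R=10.0, f_i=0.60, D_i=1.0, D_e=2.0)


@pytest.fixture
def d_opt_80():
    return PROTOCOLS["D-opt_80"]


@pytest.fixture
def noise80():
    return NoiseModel(snr=80)
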