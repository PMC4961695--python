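import numpy as np
import pytest

from moltimetable.design import default_design


@pytest.fixture(scope="session")
def design_ll():
    """24 samples every 2 h over 2 days, constant light."""
    return default_design("LL")


@pytest.fixture(scope="session")
def design_ld():
    """Same sampling, 12L:12D with lights on at t = 0."""
    return default_design("LD")


@pytest.fixture(scope="session")
def cosine_row():
    """Factory for noiseless oscillator rows: baseline*(1+sqrt2*a*cos)."""

    def make(times, baseline=10.0, a=0.3, peak=6.0, period=24.0):
        t = np.asarray(times, dtype=float)
        return baseline * (1.0 + np.sqrt(2.0) * a
                           * np.cos(2.0 * np.pi * (t - peak) / period))

    return make
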