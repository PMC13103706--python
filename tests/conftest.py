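import numpy as np
import pytest

from bioflash import FlashModel, PhotonTimeSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def exp_decay_series():
    """Instantaneous-rise single-exponential decay, 1-ms bins, no noise.

    I(t) = A exp(-t/tau) with tau = 100 ms and A = 1e4 counts/bin, preceded
    by 50 empty bins on a zero background.
    """
    tau_ms, amp, lead = 100.0, 1.0e4, 50
    n = 4000
    t_ms = np.arange(n - lead)  # bin centers relative to the peak bin
    counts = np.zeros(n)
    counts[lead:] = amp * np.exp(-t_ms / tau_ms)
    return PhotonTimeSeries(counts=counts, bin_width=0.001), tau_ms, amp, lead


def single_flash_model(amp_counts_per_bin, bin_width, **kwargs):
    """FlashModel with its peak rate set from a counts-per-bin amplitude."""
    kwargs.setdefault("onset_time", 0.5)
    kwargs.setdefault("background_rate", 0.0)
    return FlashModel(amplitude=amp_counts_per_bin / bin_width, **kwargs)
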