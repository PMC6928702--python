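import numpy as np
import pytest

from gaitwb.io_preprocess import PitchSignal


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_bump_signal(
    bump_times,
    bump_amps,
    duration,
    fs=100.0,
    width=0.05,
    side="left",
    filtered=True,
):
    """A signal of isolated Gaussian bumps at known times/amplitudes."""
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for tc, a in zip(bump_times, bump_amps):
        x += a * np.exp(-0.5 * ((t - tc) / width) ** 2)
    return PitchSignal(side=side, sampling_rate=fs, values=x, filtered=filtered)


@pytest.fixture
def bump_signal():
    return make_bump_signal
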