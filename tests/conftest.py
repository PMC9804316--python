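"""Shared fixtures: the reference periphery and cached pipeline runs.

The hair-cell stage is the slowest step, so transduced signals for the
stimuli that several tests share are computed once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from pitchmodel import periphery, stimuli

SR = 44100.0


@pytest.fixture(scope="session")
def fb():
    """The reference 50-channel log-spaced 300-3000 Hz filterbank."""
    return periphery.design_filterbank(50, 300.0, 3000.0, SR)


@pytest.fixture(scope="session")
def transduce(fb):
    """waveform -> hair-cell MultiChannelSignal, cached by key."""
    cache: dict = {}

    def _run(key: str, w: stimuli.Waveform) -> periphery.MultiChannelSignal:
        if key not in cache:
            cache[key] = periphery.ihc_transduce(periphery.apply_filterbank(w, fb))
        return cache[key]

    return _run


SWEEP_SPECS = {
    "up_wide": stimuli.SweepSpec(500, 2000, 0.040),
    "down_wide": stimuli.SweepSpec(2000, 500, 0.040),
    "up_narrow": stimuli.SweepSpec(600, 900, 0.040),
    "down_narrow": stimuli.SweepSpec(900, 600, 0.040),
}


@pytest.fixture(scope="session")
def sweep_hc(transduce):
    """Hair-cell outputs of the four 40-ms reference sweeps."""
    return {
        name: transduce(name, stimuli.make_linear_fm(spec, SR))
        for name, spec in SWEEP_SPECS.items()
    }


@pytest.fixture(scope="session")
def tone500_hc(transduce):
    return transduce("tone500", stimuli.make_pure_tone(500.0, 0.150, SR))


def dominant_frequency(x: np.ndarray, sample_rate: float) -> float:
    """Frequency of the largest non-DC FFT magnitude bin (test oracle)."""
    x = np.asarray(x, dtype=float)
    mag = np.abs(np.fft.rfft(x - x.mean()))
    freqs = np.fft.rfftfreq(x.size, 1.0 / sample_rate)
    return float(freqs[np.argmax(mag)])
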