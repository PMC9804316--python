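"""Peripheral auditory front end: gammatone filterbank and inner-hair-cell stage.

The filterbank is a bank of 4th-order Slaney-type gammatone filters
(``scipy.signal.gammatone``; bandwidth 1.019 * ERB(cf) with the
Glasberg-Moore ERB rule ``ERB(f) = 24.7 * (4.37 f/1000 + 1)``).  Centre
frequencies are geometrically (log) spaced between ``cf_low`` and
``cf_high`` inclusive — deliberately log spacing, not the more common
ERB-rate spacing.

Transduction to a nonnegative neural-drive signal uses the Meddis hair-cell
reservoir model with the classic 1986/88 constants.  The filterbank output
of a peak-amplitude-1 stimulus is multiplied by a global gain (default 100)
to place it mid-range in the model's dynamic operating region; the same
gain is used for every analysis so comparisons are internally consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import scipy.signal

from .stimuli import Waveform

__all__ = [
    "FilterbankSpec",
    "MultiChannelSignal",
    "erb",
    "design_filterbank",
    "apply_filterbank",
    "ihc_transduce",
    "apply_nonlinearity",
    "DEFAULT_IHC_GAIN",
]

#: global input gain into the Meddis stage (dimensionless); places a peak-1
#: tone mid-range in the hair-cell model's ~40 dB dynamic range
DEFAULT_IHC_GAIN = 100.0


def erb(cf: float | np.ndarray) -> float | np.ndarray:
    """Equivalent rectangular bandwidth (Hz) at centre frequency ``cf`` (Hz)."""
    return 24.7 * (4.37 * np.asarray(cf) / 1000.0 + 1.0)


@dataclass(frozen=True)
class FilterbankSpec:
    """Bank of gammatone filters with log-spaced centre frequencies."""

    n_channels: int
    cf_low: float
    cf_high: float
    sample_rate: float
    cfs: np.ndarray

    @property
    def channel_range(self) -> tuple[float, float]:
        """(lowest CF, highest CF) in Hz — the band integrated downstream."""
        return float(self.cfs[0]), float(self.cfs[-1])


@dataclass(frozen=True)
class MultiChannelSignal:
    """Channels x time matrix at one peripheral stage, with per-channel CFs."""

    data: np.ndarray
    cfs: np.ndarray
    sample_rate: float
    stage: str  # "filterbank" | "haircell" | "nonlinear"

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[0] != len(self.cfs):
            raise ValueError("data must be (n_channels, n_samples) matching cfs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sample_rate

    def channel(self, cf: float) -> np.ndarray:
        """The single channel whose CF is nearest ``cf`` (Hz)."""
        return self.data[int(np.argmin(np.abs(self.cfs - cf)))]


def design_filterbank(
    n_channels: int = 50,
    cf_low: float = 300.0,
    cf_high: float = 3000.0,
    sample_rate: float = 44100.0,
) -> FilterbankSpec:
    """Geometric CF ladder from ``cf_low`` to ``cf_high`` inclusive.

    Adjacent CFs have the constant ratio ``(cf_high/cf_low)**(1/(n-1))``.
    """
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if cf_low >= cf_high:
        raise ValueError("cf_low must be below cf_high")
    if cf_high >= sample_rate / 2:
        raise ValueError("cf_high at or above Nyquist")
    cfs = cf_low * (cf_high / cf_low) ** (np.arange(n_channels) / (n_channels - 1))
    return FilterbankSpec(n_channels, cf_low, cf_high, sample_rate, cfs)


@lru_cache(maxsize=512)
def _gammatone_sos(cf: float, sample_rate: float) -> np.ndarray:
    b, a = scipy.signal.gammatone(cf, "iir", fs=sample_rate)
    return scipy.signal.tf2sos(b, a)


def apply_filterbank(w: Waveform, fb: FilterbankSpec) -> MultiChannelSignal:
    """Filter the waveform through every gammatone channel (linear stage)."""
    if len(w) == 0:
        raise ValueError("empty waveform")
    if abs(w.sample_rate - fb.sample_rate) > 1e-9:
        raise ValueError("waveform / filterbank sample-rate mismatch")
    out = np.empty((fb.n_channels, len(w)))
    for i, cf in enumerate(fb.cfs):
        out[i] = scipy.signal.sosfilt(_gammatone_sos(float(cf), fb.sample_rate), w.samples)
    return MultiChannelSignal(out, fb.cfs, fb.sample_rate, "filterbank")


# Meddis (1986/88) hair-cell constants, Slaney Auditory Toolbox parameterization
_MEDDIS = dict(A=5.0, B=300.0, g=2000.0, y=5.05, l=2500.0, r=6580.0, x=66.31, m=1.0, h=50000.0)


def ihc_transduce(mcs: MultiChannelSignal, gain: float = DEFAULT_IHC_GAIN) -> MultiChannelSignal:
    """Meddis hair-cell transduction of every filterbank channel.

    The reservoir state starts at its silent steady state, so silence maps to
    a constant spontaneous output level.  Output is nonnegative and bounded
    by the transmitter capacity; phase-locked modulation at the stimulus
    frequency survives for frequencies well below ~4-5 kHz.
    """
    if mcs.stage != "filterbank":
        raise ValueError(f"expected a filterbank-stage signal, got stage={mcs.stage!r}")
    A, B = _MEDDIS["A"], _MEDDIS["B"]
    g, y_, l, r, x_, m, h = (
        _MEDDIS["g"], _MEDDIS["y"], _MEDDIS["l"], _MEDDIS["r"],
        _MEDDIS["x"], _MEDDIS["m"], _MEDDIS["h"],
    )
    dt = 1.0 / mcs.sample_rate
    n_ch, n = mcs.data.shape

    kt0 = g * A / (A + B)
    spont = m * y_ * kt0 / (l * kt0 + y_ * (l + r))
    q = np.full(n_ch, spont * (l + r) / kt0)
    c = np.full(n_ch, spont)
    wst = np.full(n_ch, spont * r / x_)

    ymdt, ydt, xdt, rdt, lplusrdt, gdt = y_ * m * dt, y_ * dt, x_ * dt, r * dt, (l + r) * dt, g * dt
    out = np.empty_like(mcs.data)
    drive = mcs.data * gain
    for i in range(n):
        st = np.maximum(drive[:, i] + A, 0.0)
        kt = gdt * st / (st + B)
        replenish = np.maximum(ymdt - ydt * q, 0.0)
        eject = kt * q
        loss = lplusrdt * c
        reuptake = rdt * c
        reprocess = xdt * wst
        q += replenish - eject + reprocess
        c += eject - loss
        wst += reuptake - reprocess
        out[:, i] = c
    np.maximum(out, 0.0, out=out)
    return MultiChannelSignal(out * (h * dt), mcs.cfs, mcs.sample_rate, "haircell")


def apply_nonlinearity(mcs: MultiChannelSignal, exponent: int) -> MultiChannelSignal:
    """Element-wise square or cube (sign-preserving), enhancing response ridges."""
    if exponent not in (2, 3):
        raise ValueError("exponent must be 2 or 3")
    if exponent == 2:
        data = np.sign(mcs.data) * mcs.data**2 if np.any(mcs.data < 0) else mcs.data**2
    else:
        data = mcs.data**3
    return MultiChannelSignal(data, mcs.cfs, mcs.sample_rate, "nonlinear")
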