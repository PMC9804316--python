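"""Envelope / fine-structure asymmetry of filtered sweeps, and long-term spectra.

An auditory filter responds asymmetrically in time to otherwise
time-symmetric up and down FM sweeps: the envelope declines differently and
the fine-structure (carrier) variance redistributes toward the sweep's
high-frequency end, which carries greater spectral energy within a high-CF
channel.  These envelope and AC-amplitude differences are dynamic timbre and
loudness cues that exist even when no autocorrelation pitch cue does.

At the same time the *long-term magnitude spectra* of up and down sweeps
over the same band are identical (one is the time reverse of the other);
only their phase spectra differ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal

from .stimuli import Waveform

__all__ = [
    "EnvelopeDecomposition",
    "SpectrumPair",
    "AsymmetrySummary",
    "AsymmetryReport",
    "decompose",
    "asymmetry_report",
    "long_term_spectra",
]


@dataclass(frozen=True)
class EnvelopeDecomposition:
    """Hilbert envelope and band-limited carrier of one filter channel."""

    envelope: np.ndarray  # magnitude of the analytic signal, >= 0
    fine_structure: np.ndarray  # the real band-limited carrier
    channel_cf: float
    sample_rate: float

    @property
    def duration(self) -> float:
        return self.envelope.size / self.sample_rate


@dataclass(frozen=True)
class SpectrumPair:
    """Full-length DFT magnitude and unwrapped phase."""

    frequencies: np.ndarray
    magnitude: np.ndarray
    phase: np.ndarray  # radians, unwrapped


@dataclass(frozen=True)
class AsymmetrySummary:
    """Scalar temporal-asymmetry descriptors of one filtered sweep."""

    envelope_centroid: float  # amplitude-weighted mean time, s
    terminal_initial_ratio: float  # mean envelope, last tenth / first tenth
    variance_times: np.ndarray  # centres of the sliding windows, s
    fine_structure_variance: np.ndarray  # per-window carrier variance


@dataclass(frozen=True)
class AsymmetryReport:
    """Up-vs-down temporal asymmetry.

    Since the down sweep is the time reverse of the up sweep, a filter that
    were symmetric in time (zero phase) would make the down response exactly
    the mirror image of the up response.  The difference statistics therefore
    compare the up response against the *time-mirrored* down response: they
    vanish for a zero-phase filter and are nonzero exactly when the filter
    responds asymmetrically in time (as causal auditory filters do).
    """

    up: AsymmetrySummary
    down: AsymmetrySummary  # summary of the down response on its own time axis
    centroid_difference: float  # up centroid - mirrored-down centroid, s
    ratio_difference: float  # up terminal/initial - mirrored-down terminal/initial
    max_variance_difference: float  # max |up var profile - mirrored-down profile|

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.up.variance_times,
                "up_variance": self.up.fine_structure_variance,
                "down_variance": self.down.fine_structure_variance,
            }
        )


def decompose(channel: np.ndarray, cf: float, sample_rate: float) -> EnvelopeDecomposition:
    """Hilbert envelope + fine structure of a single filtered channel."""
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty channel")
    analytic = scipy.signal.hilbert(channel)
    return EnvelopeDecomposition(np.abs(analytic), channel, cf, sample_rate)


def _summary(
    d: EnvelopeDecomposition, window: float, hop: float, edge_fraction: float
) -> AsymmetrySummary:
    n = d.envelope.size
    t = np.arange(n) / d.sample_rate
    total = d.envelope.sum()
    centroid = float((t * d.envelope).sum() / total) if total > 0 else 0.0
    k = max(1, int(round(edge_fraction * n)))
    first, last = d.envelope[:k].mean(), d.envelope[-k:].mean()
    ratio = float(last / first) if first > 0 else np.inf
    win = max(2, int(round(window * d.sample_rate)))
    hop_n = max(1, int(round(hop * d.sample_rate)))
    starts = np.arange(0, n - win + 1, hop_n)
    var = np.array([d.fine_structure[s : s + win].var() for s in starts])
    centres = (starts + win / 2) / d.sample_rate
    return AsymmetrySummary(centroid, ratio, centres, var)


def asymmetry_report(
    up: EnvelopeDecomposition,
    down: EnvelopeDecomposition,
    window: float = 0.005,
    hop: float = 0.001,
    edge_fraction: float = 0.1,
) -> AsymmetryReport:
    """Temporal-asymmetry comparison of an up and a down sweep response.

    The 5-ms variance window matches the pitch model's integration time
    constant, so "AC amplitude" is measured on the same scale the pitch
    statistic operates at.
    """
    if up.envelope.size != down.envelope.size:
        raise ValueError("up/down durations differ")
    su = _summary(up, window, hop, edge_fraction)
    sd = _summary(down, window, hop, edge_fraction)
    mirrored = EnvelopeDecomposition(
        down.envelope[::-1], down.fine_structure[::-1], down.channel_cf, down.sample_rate
    )
    sm = _summary(mirrored, window, hop, edge_fraction)
    return AsymmetryReport(
        up=su,
        down=sd,
        centroid_difference=su.envelope_centroid - sm.envelope_centroid,
        ratio_difference=su.terminal_initial_ratio - sm.terminal_initial_ratio,
        max_variance_difference=float(
            np.max(np.abs(su.fine_structure_variance - sm.fine_structure_variance))
        ),
    )


def long_term_spectra(w: Waveform) -> SpectrumPair:
    """Full-length DFT magnitude and unwrapped phase of a waveform."""
    if len(w) == 0:
        raise ValueError("empty waveform")
    spec = np.fft.rfft(w.samples)
    freqs = np.fft.rfftfreq(len(w), 1.0 / w.sample_rate)
    return SpectrumPair(freqs, np.abs(spec), np.unwrap(np.angle(spec)))
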