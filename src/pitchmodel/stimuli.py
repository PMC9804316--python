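"""Stimulus synthesis: pure tones, tone pairs, linear FM sweeps and rhythmic cues.

Every analysis in this package starts from a synthesized :class:`Waveform`;
there is no external audio input. Conventions:

* amplitudes are dimensionless with peak <= 1 (before WAV quantization);
* all on/off ramps are raised-cosine (Tukey taper), symmetric in time;
* pure tones start at zero phase (``sin``);
* linear FM sweeps use a cosine carrier whose phase is referenced to the
  sweep's temporal midpoint, so that a down sweep is *exactly* the
  time-reversed up sweep over the same band.  This identity is what makes
  the long-term magnitude spectra of up and down sweeps equal to machine
  precision while their phase spectra differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile
from scipy.signal.windows import tukey

__all__ = [
    "DEFAULT_SAMPLE_RATE",
    "DEFAULT_RAMP",
    "SEMITONE",
    "Waveform",
    "SweepSpec",
    "RhythmicCueSpec",
    "nominal_isi",
    "make_pure_tone",
    "make_linear_fm",
    "make_tone_pair",
    "make_rhythmic_cue",
    "make_continuous_cue",
    "make_silence",
    "write_wav",
    "read_wav",
    "AUDIO_DEMOS",
    "audio_demo",
]

DEFAULT_SAMPLE_RATE = 44100.0
#: default raised-cosine rise/decay time in seconds (the one duration the
#: source stimuli state explicitly, used for all stimuli for consistency)
DEFAULT_RAMP = 0.005
#: musical semitone frequency ratio
SEMITONE = 2.0 ** (1.0 / 12.0)

#: nominal rhythmic-cue rates (Hz) -> exact inter-stimulus intervals (s).
#: The rate labels are rounded; the ISIs are the primary quantities.
_NOMINAL_ISI = {1.1: 0.900, 1.4: 0.700, 1.7: 0.600, 2.0: 0.500, 2.5: 0.400}


def nominal_isi(rate: float) -> float:
    """Map a nominal cue rate (Hz) to its inter-stimulus interval (s).

    Rates 1.1/1.4/1.7/2/2.5 Hz are conventional labels for ISIs of
    900/700/600/500/400 ms; any other rate maps to ``1/rate``.
    """
    for r, isi in _NOMINAL_ISI.items():
        if abs(rate - r) < 1e-9:
            return isi
    return 1.0 / rate


@dataclass(frozen=True)
class Waveform:
    """Mono sampled audio: dimensionless amplitude samples at ``sample_rate`` Hz."""

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValueError("Waveform samples must be one-dimensional")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if samples.size and np.max(np.abs(samples)) > 1.0 + 1e-9:
            raise ValueError("Waveform peak amplitude exceeds 1")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds."""
        return self.samples.size / self.sample_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds (``n / sample_rate``)."""
        return np.arange(self.samples.size) / self.sample_rate


@dataclass(frozen=True)
class SweepSpec:
    """Linear FM sweep parameters: edge frequencies, duration and ramp time."""

    f_start: float
    f_end: float
    duration: float
    ramp: float = DEFAULT_RAMP

    def __post_init__(self) -> None:
        if self.f_start <= 0 or self.f_end <= 0:
            raise ValueError("sweep edge frequencies must be positive")
        if self.duration <= 0:
            raise ValueError("sweep duration must be positive")
        if self.ramp < 0 or 2 * self.ramp > self.duration:
            raise ValueError("need 0 <= 2*ramp <= duration")

    def reversed(self) -> "SweepSpec":
        """The same band swept in the opposite direction."""
        return replace(self, f_start=self.f_end, f_end=self.f_start)


@dataclass(frozen=True)
class RhythmicCueSpec:
    """Rhythmic cue: ``n_cycles`` carrier tones at a fixed onset-to-onset ISI.

    ``duty`` is the fraction of each period the tone is on (0.5 = square-wave
    timing).  ``isi`` defaults to ``1/rate``; use :meth:`from_nominal_rate`
    for the conventional rate labels whose ISIs are round numbers.
    """

    rate: float
    n_cycles: int = 4
    duty: float = 0.5
    carrier_freq: float = 500.0
    ramp: float = DEFAULT_RAMP
    isi: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.n_cycles < 1:
            raise ValueError("need n_cycles >= 1")
        if not 0.0 < self.duty <= 1.0:
            raise ValueError("duty must be in (0, 1]")
        if self.carrier_freq <= 0:
            raise ValueError("carrier_freq must be positive")
        if self.isi == 0.0:
            object.__setattr__(self, "isi", 1.0 / self.rate)

    @classmethod
    def from_nominal_rate(cls, rate: float, **kwargs) -> "RhythmicCueSpec":
        """Build a spec from a nominal rate label (ISI from :func:`nominal_isi`)."""
        return cls(rate=rate, isi=nominal_isi(rate), **kwargs)

    @property
    def tone_duration(self) -> float:
        """On-period of each cue tone: ``duty * isi`` seconds."""
        return self.duty * self.isi


def _n_samples(duration: float, sample_rate: float) -> int:
    return int(round(duration * sample_rate))


def _ramp_window(n: int, ramp: float, duration: float) -> np.ndarray:
    """Symmetric raised-cosine (Tukey) on/off taper."""
    if n == 0:
        return np.zeros(0)
    alpha = min(1.0, 2.0 * ramp / duration) if duration > 0 else 0.0
    if alpha < 1e-9:  # sub-sample taper: rectangular
        return np.ones(n)
    return tukey(n, alpha, sym=True)


def _check_tone_args(freq: float, duration: float, sample_rate: float, ramp: float) -> None:
    if freq >= sample_rate / 2:
        raise ValueError(f"frequency {freq} Hz is at or above Nyquist ({sample_rate / 2} Hz)")
    if freq <= 0:
        raise ValueError("frequency must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if ramp < 0 or 2 * ramp > duration:
        raise ValueError("need 0 <= 2*ramp <= duration")


def make_pure_tone(
    freq: float,
    duration: float,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    ramp: float = DEFAULT_RAMP,
) -> Waveform:
    """Sinusoid at ``freq`` Hz with raised-cosine on/off ramps, zero start phase."""
    _check_tone_args(freq, duration, sample_rate, ramp)
    n = _n_samples(duration, sample_rate)
    t = np.arange(n) / sample_rate
    x = np.sin(2 * np.pi * freq * t) * _ramp_window(n, ramp, duration)
    return Waveform(x, sample_rate)


def make_linear_fm(spec: SweepSpec, sample_rate: float = DEFAULT_SAMPLE_RATE) -> Waveform:
    """Linear FM sweep from ``f_start`` to ``f_end`` Hz over ``duration`` s.

    Instantaneous frequency is interpolated linearly between the edge
    frequencies across the sampled support; the carrier is a cosine with
    phase referenced to the sweep midpoint (see module docstring).  A
    degenerate sweep (``f_start == f_end``) reduces to :func:`make_pure_tone`.
    """
    nyq = sample_rate / 2
    if spec.f_start >= nyq or spec.f_end >= nyq:
        raise ValueError("sweep edge frequency at or above Nyquist")
    if spec.f_start == spec.f_end:
        return make_pure_tone(spec.f_start, spec.duration, sample_rate, spec.ramp)
    n = _n_samples(spec.duration, sample_rate)
    if n < 2:
        raise ValueError("sweep too short for this sample rate")
    t = np.arange(n) / sample_rate
    span = (n - 1) / sample_rate  # time of the last sample
    k = (spec.f_end - spec.f_start) / span  # sweep rate, Hz/s
    phase = 2 * np.pi * (spec.f_start * t + 0.5 * k * t * t)
    total_phase = 2 * np.pi * span * (spec.f_start + spec.f_end) / 2
    x = np.cos(phase - total_phase / 2)
    return Waveform(x * _ramp_window(n, spec.ramp, spec.duration), sample_rate)


def make_tone_pair(
    standard_freq: float,
    semitone_offset: float,
    tone_duration: float = 0.150,
    gap: float = 0.350,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    ramp: float = DEFAULT_RAMP,
) -> Waveform:
    """Standard tone, silent gap, then a comparison tone ``semitone_offset``
    semitones away (ratio ``2**(offset/12)``).  Segments are independently
    ramped; no cross-segment phase continuity is imposed."""
    if gap < 0:
        raise ValueError("gap must be nonnegative")
    comparison_freq = standard_freq * SEMITONE**semitone_offset
    std = make_pure_tone(standard_freq, tone_duration, sample_rate, ramp)
    cmp_ = make_pure_tone(comparison_freq, tone_duration, sample_rate, ramp)
    silence = np.zeros(_n_samples(gap, sample_rate))
    return Waveform(np.concatenate([std.samples, silence, cmp_.samples]), sample_rate)


def make_rhythmic_cue(
    spec: RhythmicCueSpec, sample_rate: float = DEFAULT_SAMPLE_RATE
) -> tuple[Waveform, list[float]]:
    """Rhythmic tone sequence; returns the waveform and the tone onset times.

    Tone ``k`` (k = 0..n_cycles-1) starts at ``k * isi`` and lasts
    ``duty * isi`` seconds; the waveform ends at the last tone's offset.
    """
    if spec.carrier_freq >= sample_rate / 2:
        raise ValueError("carrier at or above Nyquist")
    tone = make_pure_tone(spec.carrier_freq, spec.tone_duration, sample_rate, spec.ramp)
    total = (spec.n_cycles - 1) * spec.isi + spec.tone_duration
    out = np.zeros(_n_samples(total, sample_rate))
    onsets = [k * spec.isi for k in range(spec.n_cycles)]
    for t0 in onsets:
        i0 = _n_samples(t0, sample_rate)
        out[i0 : i0 + len(tone)] = tone.samples[: max(0, out.size - i0)]
    return Waveform(out, sample_rate), onsets


def make_continuous_cue(
    spec: RhythmicCueSpec,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    full_final_period: bool = False,
) -> Waveform:
    """Continuous pure-tone cue matched in duration to the rhythmic cue.

    By default the tone ends where the rhythmic cue's last tone ends,
    i.e. duration ``(n_cycles - 1 + duty) * isi``; with
    ``full_final_period=True`` it spans ``n_cycles * isi``.
    """
    duration = (spec.n_cycles - (0.0 if full_final_period else 1.0 - spec.duty)) * spec.isi
    return make_pure_tone(spec.carrier_freq, duration, sample_rate, spec.ramp)


def make_silence(duration: float, sample_rate: float = DEFAULT_SAMPLE_RATE) -> Waveform:
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    return Waveform(np.zeros(_n_samples(duration, sample_rate)), sample_rate)


def write_wav(w: Waveform, path, subtype: str = "PCM_16") -> None:
    """Write a waveform as a mono WAV file (``PCM_16`` or ``FLOAT``)."""
    rate = int(round(w.sample_rate))
    if subtype == "PCM_16":
        scaled = np.clip(np.round(w.samples * 32768.0), -32768, 32767).astype(np.int16)
        wavfile.write(path, rate, scaled)
    elif subtype == "FLOAT":
        wavfile.write(path, rate, w.samples.astype(np.float32))
    else:
        raise ValueError(f"unsupported WAV subtype {subtype!r}")


def read_wav(path) -> Waveform:
    """Read a mono WAV file back into a :class:`Waveform` (amplitude in [-1, 1])."""
    rate, data = wavfile.read(path)
    if data.ndim != 1:
        raise ValueError("only mono WAV files are supported")
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in (np.float32, np.float64):
        samples = np.clip(data.astype(np.float64), -1.0, 1.0)
    else:
        raise ValueError(f"unsupported WAV sample format {data.dtype}")
    return Waveform(samples, float(rate))


#: audio demonstration presets: up sweep then down sweep over the same band
AUDIO_DEMOS: dict[str, SweepSpec] = {
    "S1": SweepSpec(5500.0, 7000.0, 0.040),
    "S2": SweepSpec(500.0, 2000.0, 0.010),
    "S3": SweepSpec(500.0, 2000.0, 0.040),
    "S4": SweepSpec(600.0, 900.0, 0.040),
}


def audio_demo(
    name: str, sample_rate: float = DEFAULT_SAMPLE_RATE, gap: float = 0.5
) -> Waveform:
    """Demo waveform ``name`` in {S1..S4}: up sweep, silence, down sweep."""
    try:
        spec = AUDIO_DEMOS[name]
    except KeyError:
        raise ValueError(f"unknown audio demo {name!r}; choose from {sorted(AUDIO_DEMOS)}")
    up = make_linear_fm(spec, sample_rate)
    down = make_linear_fm(spec.reversed(), sample_rate)
    silence = np.zeros(_n_samples(gap, sample_rate))
    return Waveform(np.concatenate([up.samples, silence, down.samples]), sample_rate)
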