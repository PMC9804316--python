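"""Summary autocorrelation (SACF) pitch extraction.

The model statistic is the Licklider-style exponentially weighted,
channel-integrated autocorrelation of the peripheral (hair-cell) output

    R_t(tau) = sum over channels f in [f_l, f_u], sum over past time T >= 0 of
               x(f, t - T) * x(f, t - tau - T) * exp(-T / decay_tau) * dT * df

where ``x`` is each channel's transduced waveform AC-coupled by the matching
window mean (the hair-cell model's standing spontaneous and rectification
offset carries no periodicity information and would otherwise dominate the
normalized correlogram), i.e. the statistic is a weighted covariance.  Two
forms are provided:

* :func:`sacf` / :func:`running_sacf` — the time-resolved statistic above,
  with a 5-ms decay by default; it tracks pitch cues dynamically through a
  stimulus.
* :func:`stimulus_sacf` — the infinite-time-constant limit: the whole-segment
  channel-summed autocovariance, equivalently the running statistic
  integrated over the stimulus.  This is the stimulus-level summary pitch
  decisions are read from.  Its finite-signal lag taper makes a tone's
  first-period peak the global one, and it smears the drifting
  instantaneous-period structure of an FM sweep, so a brief sweep yields no
  qualifying peak while a tone does.

A peak at non-zero lag ``tau`` is a pitch estimate at ``1/tau`` Hz; the
*absence* of such a peak is an explicit, first-class outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.signal

from .periphery import MultiChannelSignal

__all__ = [
    "DEFAULT_DECAY_TAU",
    "DEFAULT_LAG_MAX",
    "SACF",
    "PeakCriteria",
    "PitchEstimate",
    "CurvatureResult",
    "sacf",
    "stimulus_sacf",
    "running_sacf",
    "estimate_pitch",
    "estimate_running_pitch",
    "sacf_curvature",
]

#: exponential-decay time constant of the running autocorrelation memory, s
DEFAULT_DECAY_TAU = 0.005
#: default maximum autocorrelation lag, s (covers pitches down to 80 Hz)
DEFAULT_LAG_MAX = 0.0125
#: the past-time integral is truncated where its kernel falls below e^-5
_TRUNCATION_TAUS = 5.0


@dataclass(frozen=True)
class SACF:
    """Normalized summary autocorrelation over a lag axis.

    ``eval_time`` is the evaluation instant for the time-resolved form, or
    the segment end for the stimulus-level form (``decay_tau = inf``).
    """

    lags: np.ndarray  # seconds, uniformly spaced from 0
    amplitude: np.ndarray  # normalized so amplitude[0] == 1
    eval_time: float
    decay_tau: float
    channel_range: tuple[float, float]


@dataclass(frozen=True)
class PeakCriteria:
    """Operational definition of a 'peak at a non-zero lag'.

    ``lag_min`` excludes the zero-lag main lobe (0.5 ms clears it for the
    300-3000 Hz band).  ``salience_threshold`` and ``prominence`` are in
    normalized SACF units; the defaults are calibrated on the stimulus-level
    SACF so that steady tones in 300-1000 Hz qualify (salience >= 0.95)
    while 40-ms FM sweeps do not (salience <= 0.80).  ``tie_tolerance``
    resolves the period ambiguity of near-stationary frames: among peaks
    within it of the maximum salience, the shortest lag (highest frequency)
    wins, as a periodic signal peaks equally at every period multiple.
    """

    lag_min: float = 0.0005
    salience_threshold: float = 0.87
    prominence: float = 0.05
    tie_tolerance: float = 0.02

    def __post_init__(self) -> None:
        if self.lag_min <= 0:
            raise ValueError("lag_min must be positive")
        if not (0 < self.salience_threshold < 1 and 0 < self.prominence < 1):
            raise ValueError("thresholds must be in (0, 1)")


@dataclass(frozen=True)
class PitchEstimate:
    """Best qualifying SACF peak, or an explicit absence (``found=False``)."""

    found: bool
    lag: float | None = None
    frequency: float | None = None
    salience: float | None = None
    criteria: PeakCriteria = field(default_factory=PeakCriteria)


def _check_stage(mcs: MultiChannelSignal) -> None:
    if mcs.stage not in ("haircell", "nonlinear"):
        raise ValueError("SACF input must be hair-cell or nonlinear stage output")


def _ac_coupled(data: np.ndarray) -> np.ndarray:
    return data - data.mean(axis=1, keepdims=True)


def _normalize(raw: np.ndarray, gross_power: float | None = None) -> np.ndarray:
    """Divide by the lag-0 value; a degenerate window (no AC energy beyond
    numerical cancellation noise) maps to a delta at lag 0."""
    floor = 0.0 if gross_power is None else 1e-10 * gross_power
    if raw[0] > floor:
        return raw / raw[0]
    out = np.zeros_like(raw)
    out[0] = 1.0
    return out


def _sacf_at_index(
    data: np.ndarray, sample_rate: float, eval_index: int, n_lags: int, decay_tau: float
) -> np.ndarray:
    """Exponentially weighted local covariance at sample ``eval_index``
    ('current' sample, inclusive).

    For each lag the two signal windows are AC-coupled by their own weighted
    window means before the correlation product, so constant stretches
    (spontaneous hair-cell output, pre-stimulus silence) contribute nothing.
    Before its start the signal is extended with its initial value — the
    hair cell sat at its resting state before the stimulus.
    """
    n_t = int(round(_TRUNCATION_TAUS * decay_tau * sample_rate))
    dt = 1.0 / sample_rate
    need = n_t + n_lags
    hist = data[:, max(0, eval_index + 1 - need) : eval_index + 1]
    if hist.shape[1] < need:
        pad = np.repeat(data[:, :1], need - hist.shape[1], axis=1)
        hist = np.concatenate([pad, hist], axis=1)
    z = hist[:, ::-1]  # z[:, k] = x[:, eval_index - k]
    weight = np.exp(-np.arange(n_t) * dt / decay_tau) * dt
    total_w = weight.sum()
    zw = z[:, :n_t] * weight
    mean0 = zw.sum(axis=1) / total_w
    gross = float(np.sum(zw * z[:, :n_t]))  # uncentered power, cancellation floor
    out = np.empty(n_lags)
    for lag in range(n_lags):
        seg = z[:, lag : lag + n_t]
        mean_lag = seg @ weight / total_w
        out[lag] = np.sum(zw * seg) - total_w * (mean0 @ mean_lag)
    return out, gross


def sacf(
    mcs: MultiChannelSignal,
    eval_time: float | None = None,
    lag_max: float = DEFAULT_LAG_MAX,
    decay_tau: float = DEFAULT_DECAY_TAU,
) -> SACF:
    """Time-resolved SACF at ``eval_time`` (default: the stimulus offset).

    The lag axis runs from 0 to ``lag_max`` at the signal's sample
    resolution, and the amplitude is normalized by the lag-0 value.
    """
    _check_stage(mcs)
    if lag_max <= 0:
        raise ValueError("lag_max must be positive")
    if eval_time is None:
        eval_time = mcs.duration
    if eval_time <= 0 or eval_time > mcs.duration + 1e-12:
        raise ValueError("eval_time outside the signal")
    if lag_max >= eval_time:
        raise ValueError("need lag_max < eval_time")
    sr = mcs.sample_rate
    data = mcs.data
    eval_index = min(int(round(eval_time * sr)) - 1, data.shape[1] - 1)
    n_lags = int(round(lag_max * sr)) + 1
    raw, gross = _sacf_at_index(data, sr, eval_index, n_lags, decay_tau)
    return SACF(np.arange(n_lags) / sr, _normalize(raw, gross), eval_time, decay_tau,
                (float(mcs.cfs[0]), float(mcs.cfs[-1])))


def stimulus_sacf(
    mcs: MultiChannelSignal,
    t_start: float | None = None,
    t_end: float | None = None,
    lag_max: float = DEFAULT_LAG_MAX,
) -> SACF:
    """Stimulus-level SACF: whole-segment autocovariance summed over channels.

    This is the infinite-time-constant limit of the running statistic —
    every evaluation instant of the stimulus contributes — and is the
    summary that pitch estimates are read from.  ``t_start``/``t_end``
    restrict the analysis to a segment (e.g. one tone of a tone pair).
    """
    _check_stage(mcs)
    if lag_max <= 0:
        raise ValueError("lag_max must be positive")
    sr = mcs.sample_rate
    i0 = 0 if t_start is None else max(0, int(round(t_start * sr)))
    i1 = mcs.data.shape[1] if t_end is None else min(mcs.data.shape[1], int(round(t_end * sr)))
    if i1 - i0 < 2:
        raise ValueError("analysis segment is empty")
    data = _ac_coupled(mcs.data[:, i0:i1])
    n = data.shape[1]
    n_lags = int(round(lag_max * sr)) + 1
    if n_lags > n:
        raise ValueError("lag_max exceeds the analysis segment")
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(data, nfft, axis=1)
    raw = np.fft.irfft((spec * spec.conj()).sum(axis=0).real, nfft)[:n_lags] / sr
    return SACF(np.arange(n_lags) / sr, _normalize(raw), i1 / sr, np.inf,
                (float(mcs.cfs[0]), float(mcs.cfs[-1])))


def running_sacf(
    mcs: MultiChannelSignal,
    frame_times: np.ndarray | list[float],
    lag_max: float = DEFAULT_LAG_MAX,
    decay_tau: float = DEFAULT_DECAY_TAU,
) -> list[SACF]:
    """Short-term SACF at each frame time, each normalized by its own lag 0.

    Frame times may fall early in the signal (history is zero-padded), so
    the statistic can be tracked through onset and sweep.
    """
    _check_stage(mcs)
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size == 0:
        raise ValueError("empty frame list")
    if np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame times must be strictly increasing")
    if frame_times[0] <= 0 or frame_times[-1] > mcs.duration + 1e-12:
        raise ValueError("frame times outside the signal")
    sr = mcs.sample_rate
    data = mcs.data
    n_lags = int(round(lag_max * sr)) + 1
    lags = np.arange(n_lags) / sr
    rng = (float(mcs.cfs[0]), float(mcs.cfs[-1]))
    frames = []
    for t in frame_times:
        idx = min(int(round(t * sr)) - 1, data.shape[1] - 1)
        raw, gross = _sacf_at_index(data, sr, idx, n_lags, decay_tau)
        frames.append(SACF(lags, _normalize(raw, gross), float(t), decay_tau, rng))
    return frames


def estimate_pitch(s: SACF, criteria: PeakCriteria | None = None) -> PitchEstimate:
    """Highest-salience qualifying local maximum, or ``found=False``.

    Absence of a qualifying peak is a value, not an error: brief FM sweeps
    produce none under the default criteria.
    """
    c = criteria or PeakCriteria()
    peaks, props = scipy.signal.find_peaks(
        s.amplitude, height=c.salience_threshold, prominence=c.prominence
    )
    keep = s.lags[peaks] >= c.lag_min
    peaks, heights = peaks[keep], props["peak_heights"][keep]
    if peaks.size == 0:
        return PitchEstimate(found=False, criteria=c)
    near_max = heights >= heights.max() - c.tie_tolerance
    best = int(np.argmax(near_max))  # shortest qualifying lag among ties
    lag = float(s.lags[peaks[best]])
    return PitchEstimate(
        found=True, lag=lag, frequency=1.0 / lag, salience=float(heights[best]), criteria=c
    )


def estimate_running_pitch(
    frames: list[SACF],
    criteria: PeakCriteria | None = None,
    min_duration: float = 0.010,
    lag_tolerance: float = 0.025,
) -> PitchEstimate:
    """Sustained pitch estimate from a running-SACF frame sequence.

    A running pitch exists only if qualifying per-frame peaks keep a
    consistent lag (within ``lag_tolerance`` of the run's median) over at
    least ``min_duration`` of consecutive frames.  A steady tone produces a
    long consistent run; an FM sweep's per-frame peak tracks the drifting
    instantaneous period, so no run is sustained and no pitch is reported —
    the short-memory statistic of a slow glide is locally quasi-periodic,
    and stability over frames is what distinguishes a pitch from a chirp.
    """
    c = criteria or PeakCriteria()
    ests = [estimate_pitch(f, c) for f in frames]
    times = np.array([f.eval_time for f in frames])
    best: tuple[float, list[int]] = (0.0, [])
    i = 0
    while i < len(ests):
        if not ests[i].found:
            i += 1
            continue
        j = i
        run = [i]
        while j + 1 < len(ests) and ests[j + 1].found:
            cand = run + [j + 1]
            med = float(np.median([ests[k].lag for k in cand]))
            if all(abs(ests[k].lag - med) <= lag_tolerance * med for k in cand):
                run = cand
                j += 1
            else:
                break
        span = times[run[-1]] - times[run[0]]
        if span > best[0]:
            best = (span, run)
        i = j + 1
    span, run = best
    if span < min_duration or not run:
        return PitchEstimate(found=False, criteria=c)
    lags = [ests[k].lag for k in run]
    lag = float(np.median(lags))
    sal = float(np.median([ests[k].salience for k in run]))
    return PitchEstimate(found=True, lag=lag, frequency=1.0 / lag, salience=sal, criteria=c)


@dataclass(frozen=True)
class CurvatureResult:
    """Discrete second derivative of SACF amplitude vs. lag."""

    lags: np.ndarray  # interior lag samples the curvature is defined at
    curvature: np.ndarray
    sign_change_lags: np.ndarray  # lags where the curvature crosses zero


def sacf_curvature(s: SACF) -> CurvatureResult:
    """Second difference of the SACF; sign changes mark inflection lags.

    A narrow-band sweep can change SACF curvature sign at non-zero lag
    without producing any qualifying peak — curvature is a finer-grained
    descriptor than peak presence.
    """
    if s.amplitude.size < 3:
        raise ValueError("need at least 3 lag samples")
    curv = np.diff(s.amplitude, 2)
    lags = s.lags[1:-1]
    sign = np.sign(curv)
    idx = np.where(sign != 0)[0]
    changes = idx[1:][sign[idx[1:]] * sign[idx[:-1]] < 0]
    return CurvatureResult(lags, curv, lags[changes])
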