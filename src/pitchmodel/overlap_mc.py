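"""Monte Carlo simulation of random-target overlap with a rhythmic expectancy.

A rhythmic cue (four tones at 50% duty cycle) sets up a temporal expectancy:
had the cue continued, tones would have occurred at four more onsets after
cue offset.  When a brief target is instead placed at a uniformly random
time in the post-cue window, some fraction of "random" targets nevertheless
fall on the expectancy — either touching an expected *onset instant*
(``mode="onset"``) or intersecting the expected *full on-period*
(``mode="full_on_period"``).  This module quantifies that fraction by
simulation, run by run, together with an exact closed-form probability used
as an oracle.

Geometry (measured from cue offset): the expected onsets continue the cue's
period from the last cue tone's onset, so the k-th expected onset falls at
``duty*isi + (k-1)*isi`` for k = 1..n.  The target onset is uniform on
``[0, window - target_duration]`` with ``window = n_expected_cycles * isi``,
so the target always fits inside the four-cycle window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stimuli import nominal_isi

__all__ = [
    "OverlapConfig",
    "OverlapResult",
    "expected_windows",
    "analytic_probability",
    "simulate",
    "rate_sweep",
]

_MODES = ("onset", "full_on_period")


@dataclass(frozen=True)
class OverlapConfig:
    """Geometry and sampling plan for the overlap simulation.

    Defaults correspond to the 1.7-Hz (600-ms ISI) cue with the 40-ms FM
    target: four expected cycles, 50% duty, 5000 runs of 100 trials.
    """

    isi: float = 0.600
    n_expected_cycles: int = 4
    target_duration: float = 0.040
    duty: float = 0.5
    mode: str = "onset"
    window: float | None = None
    n_trials_per_run: int = 100
    n_runs: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.isi <= 0:
            raise ValueError("isi must be positive")
        if self.n_expected_cycles < 0:
            raise ValueError("n_expected_cycles must be nonnegative")
        if not 0.0 <= self.duty <= 1.0:
            raise ValueError("duty must be in [0, 1]")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.window is None:
            object.__setattr__(self, "window", self.n_expected_cycles * self.isi)
        if self.window < self.n_expected_cycles * self.isi - 1e-12:
            raise ValueError("window must cover the expected cycles")
        if not 0 < self.target_duration < self.window:
            raise ValueError("need 0 < target_duration < window")
        if self.n_trials_per_run < 1:
            raise ValueError("need n_trials_per_run >= 1")
        if self.n_runs < 1:
            raise ValueError("need n_runs >= 1")

    @property
    def placement_range(self) -> float:
        """Width of the uniform target-onset distribution."""
        return self.window - self.target_duration


@dataclass(frozen=True)
class OverlapResult:
    """Per-run overlap percentages with summary statistics."""

    per_run_percent: np.ndarray
    mean_percent: float
    max_percent: float
    analytic_percent: float
    config: OverlapConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"run": np.arange(1, self.per_run_percent.size + 1),
             "percent": self.per_run_percent}
        )


def expected_windows(c: OverlapConfig) -> list[tuple[float, float]]:
    """Expectancy intervals (start, end) in seconds after cue offset.

    In onset mode each window is the degenerate instant ``[t_k, t_k]``; in
    full-on-period mode it is ``[t_k, t_k + duty*isi]``.
    """
    out = []
    for k in range(1, c.n_expected_cycles + 1):
        t_k = c.duty * c.isi + (k - 1) * c.isi
        end = t_k + (c.duty * c.isi if c.mode == "full_on_period" else 0.0)
        out.append((t_k, end))
    return out


def _favourable_intervals(c: OverlapConfig) -> list[tuple[float, float]]:
    """Target-onset intervals that produce an overlap, clipped to the
    placement range, merged into a disjoint union."""
    lo, hi = 0.0, c.placement_range
    raw = []
    for start, end in expected_windows(c):
        a, b = max(lo, start - c.target_duration), min(hi, end)
        if b >= a:
            raw.append((a, b))
    raw.sort()
    merged: list[tuple[float, float]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], b))
        else:
            merged.append((a, b))
    return merged


def analytic_probability(c: OverlapConfig) -> float:
    """Exact overlap probability by interval-union arithmetic.

    The target ``[onset, onset + target_duration]`` intersects the window
    ``[s, e]`` iff ``onset`` lies in ``[s - target_duration, e]``; the
    probability is the measure of the union of those favourable intervals
    inside the placement range, divided by the placement range.
    """
    if c.placement_range <= 0:
        return 1.0
    total = sum(b - a for a, b in _favourable_intervals(c))
    return total / c.placement_range


def simulate(c: OverlapConfig) -> OverlapResult:
    """Monte Carlo estimate of the overlap percentage, run by run.

    Each run draws ``n_trials_per_run`` uniform target onsets; the per-run
    percentage is the fraction of trials whose target interval intersects
    any expectancy window (closed-interval predicate).  Reproducible for a
    given seed.
    """
    rng = np.random.default_rng(c.seed)
    onsets = rng.uniform(0.0, c.placement_range, size=(c.n_runs, c.n_trials_per_run))
    hit = np.zeros(onsets.shape, dtype=bool)
    for start, end in expected_windows(c):
        hit |= (onsets <= end) & (onsets + c.target_duration >= start)
    per_run = hit.mean(axis=1) * 100.0
    return OverlapResult(
        per_run_percent=per_run,
        mean_percent=float(per_run.mean()),
        max_percent=float(per_run.max()),
        analytic_percent=100.0 * analytic_probability(c),
        config=c,
    )


def rate_sweep(rates: list[float], base: OverlapConfig | None = None) -> pd.DataFrame:
    """Run the simulation at each nominal cue rate (same seed per rate).

    ISIs come from :func:`pitchmodel.stimuli.nominal_isi`, so the
    conventional rate labels map to their exact intervals (1.7 Hz -> 600 ms).
    """
    if not rates:
        raise ValueError("empty rate list")
    base = base or OverlapConfig()
    rows = []
    for rate in rates:
        cfg = replace(base, isi=nominal_isi(rate), window=None)
        res = simulate(cfg)
        rows.append(
            {"rate": rate, "isi": cfg.isi, "mean_percent": res.mean_percent,
             "max_percent": res.max_percent, "analytic_percent": res.analytic_percent}
        )
    return pd.DataFrame(rows)
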