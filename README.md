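# pitchmodel

Computational tools for a question in auditory psychophysics: **do brief
frequency-modulated (FM) sweeps carry a usable pitch cue, and how often do
"randomly timed" targets accidentally land on a rhythmically cued temporal
expectancy?** Both questions arise when interpreting forward-entrainment
experiments — studies of whether a rhythmic tone sequence improves
discrimination of a target presented after the rhythm stops.

The package is aimed at hearing scientists and psychophysicists who want to
audit stimulus designs of this kind: it synthesizes the relevant stimuli,
runs them through a standard model of the auditory periphery and an
autocorrelation model of pitch extraction, quantifies the envelope/timbre
cues that remain when pitch cues are absent, and simulates the
rhythmic-expectancy overlap statistics of random target timing.

## The model

**Pitch extraction.** Sound is passed through a bank of 50 fourth-order
gammatone filters with centre frequencies log-spaced from 300 to 3000 Hz
(bandwidth 1.019·ERB(f), ERB(f) = 24.7·(4.37·f/1000 + 1)), then through a
Meddis inner-hair-cell model (reservoir dynamics, 1986/88 constants), giving
a nonnegative neural-drive signal x(f, t) per channel. The pitch statistic
is the exponentially weighted, channel-integrated autocorrelation

    R_t(τ) = ∫_{f_l}^{f_u} ∫_0^∞ x(f, t−T) · x(f, t−τ−T) · e^(−T/0.005) dT df

with a 5-ms decay time constant, each window AC-coupled by its own weighted
mean and the result normalized by its lag-0 value. A peak at non-zero lag τ
is a pitch estimate at 1/τ Hz. Two readouts are provided: the *running*
form above (used to track cues dynamically through a stimulus) and the
*stimulus-level* form — its infinite-time-constant limit, the whole-segment
summary that pitch decisions are read from. A 150-ms pure tone produces a
dominant peak at its period (2 ms for 500 Hz); a 40-ms linear FM sweep
produces no qualifying peak in either direction, because its periodicity
drifts throughout the sweep and never accumulates at any single lag.

**Temporal-expectancy overlap.** A 4-tone rhythmic cue at inter-stimulus
interval `isi` (50% duty cycle) sets up four expected tone positions after
its offset. A target of duration `d` placed uniformly at random in the
4-cycle window overlaps the expectancy with probability given exactly by an
interval-union formula, e.g. touching an expected *onset instant* with
P = 4d / (4·isi − d). The Monte Carlo module simulates this run by run
(default 5000 runs × 100 trials) and checks itself against the closed form.

## Worked example

```bash
$ pitchmodel overlap-sim --rate 1.7 --mode onset --runs 5000 --trials 100 --seed 1
{
  "rate_hz": 1.7,
  "isi_s": 0.6,
  "mode": "onset",
  "mean_percent": 6.825,
  "max_percent": 17.0,
  "analytic_percent": 6.78
}
```

For a 1.7-Hz cue (600-ms ISI) and a 40-ms target, about 6.8% of "random"
targets touch an expected tone onset on average, and single 100-trial runs
reach 17% — so a design that treats these trials as entrainment-free
underestimates the cued condition's advantage. With `--mode full_on_period`
(overlap with the full 300-ms expected on-period) the mean rises to ≈ 56%.

```bash
$ pitchmodel pitch --stimulus jones_pair
pitch: 501.1 Hz (lag 1.995 ms, salience 0.971)
$ pitchmodel pitch --stimulus lin_fm40
pitch: none (no qualifying non-zero-lag SACF peak)
```

The 500-Hz standard of a tone pair is recovered from its 2-ms
autocorrelation peak (501.1 Hz is the nearest lag sample to 500 Hz at
44.1 kHz); the 40-ms 500→2000-Hz sweep yields no pitch estimate, while its
up/down direction remains perfectly distinguishable through envelope and
phase-spectrum (timbre) cues — see `pitchmodel reproduce fig3` and
`pitchmodel reproduce figS1`.

Python API equivalent:

```python
from pitchmodel.cli import run_pipeline
res = run_pipeline("jones_pair")
print(res.estimate.frequency, res.estimate.salience)   # 501.1…  0.971…
```

Other entry points: `pitchmodel synth` (write stimulus WAVs),
`pitchmodel demo S1..S4` (up-then-down sweep audio demonstrations),
`pitchmodel reproduce {fig1,fig2,fig3,figS1,figS2,videoS1,videoS2,audioS1..S4}`
(figures/animations with JSON provenance records).

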