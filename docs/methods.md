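# Methods

This note documents the models implemented in `pitchmodel`, the parameter
choices that matter, and the design decisions taken where the problem was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Stimuli

All analyses run on synthesized stimuli; there is no external data path.

* **Sample rate** 44.1 kHz by default (configurable everywhere).
* **Ramps.** All on/off ramps are raised-cosine (Tukey) tapers, 5 ms by
  default, symmetric in time. Sub-sample taper requests fall back to a
  rectangular window.
* **Phase conventions.** Pure tones start at zero phase (`sin`). Linear FM
  sweeps use a cosine carrier whose phase is referenced to the sweep's
  temporal midpoint, with the sweep rate defined over the sampled support
  `(N−1)/fs`. Under this convention a down sweep is *exactly* the
  time-reversed up sweep over the same band (machine precision), which is
  what makes the long-term magnitude spectra of the two directions equal to
  1e-9 while their phase spectra differ by radians. A degenerate sweep
  (`f_start == f_end`) delegates to the pure-tone constructor, so the two
  conventions meet continuously in behaviour if not in phase.
* **Tone pairs** (standard + comparison one semitone apart, ratio 2^(1/12))
  are built from independently ramped 150-ms segments separated by a 350-ms
  gap; no cross-segment phase continuity is imposed. The 500-Hz standard
  default places the model's pitch lag near 2 ms; it is configurable.
* **Rhythmic cues.** A cue is `n_cycles` tones at onset-to-onset interval
  `isi` with duty-cycle fraction `duty` (default 4 cycles, 50%). The
  conventional rate labels 1.1/1.4/1.7/2/2.5 Hz map to the exact ISIs
  900/700/600/500/400 ms (`nominal_isi`); the ISI, not the rounded rate, is
  the primary quantity. The duration-matched continuous cue ends at the
  last rhythmic tone's offset, i.e. `(n_cycles − 1 + duty)·isi`; a flag
  extends it to the full final period instead.

What the generator does *not* emulate: presentation level and calibration,
loudspeaker/headphone transfer functions, background noise, and any
behavioural (task) structure. Passing tests therefore demonstrate
properties of the stimulus-and-model chain, not of listeners.

## Auditory periphery

* **Filterbank.** 50 fourth-order gammatone filters (the Slaney all-pole
  design as provided by `scipy.signal.gammatone`, converted to second-order
  sections), bandwidth 1.019·ERB(cf) with ERB(f) = 24.7·(4.37·f/1000 + 1).
  Centre frequencies are **log-spaced** (geometric ladder) from 300 to
  3000 Hz inclusive — deliberately not the more common ERB-rate spacing.
* **Hair cell.** Meddis reservoir model, 1986/88 constants
  (A=5, B=300, g=2000, y=5.05, l=2500, r=6580, x=66.31, m=1, h=50000),
  explicit-Euler update at the audio rate, state initialized at the silent
  steady state so silence maps to a constant spontaneous output. The
  filterbank output of a peak-1 stimulus is multiplied by a single global
  gain (default 100) placing it mid-range in the model's dynamic region;
  the same gain is used for every analysis so that comparisons across
  stimuli are internally consistent. No outer/middle ear, no stochastic
  spike generation.
* **Optional nonlinearity.** An element-wise square or (sign-preserving)
  cube of the hair-cell output, which sharpens response ridges and
  measurably raises the residual secondary-peak salience of a 40-ms sweep —
  the "forced weak pitch cue" configuration.

## The autocorrelation pitch statistic

The core statistic is the exponentially weighted, channel-integrated
autocorrelation of the hair-cell output (5-ms decay). Implementation
definitions that the equation alone does not fix:

* **AC coupling.** The hair-cell output carries a standing offset
  (spontaneous rate plus rectification DC) with no periodicity information;
  left in place it dominates the normalized correlogram (background ≈ 0.8–1
  at all lags). Each correlation window is therefore centred on its own
  weighted mean — the statistic is a windowed covariance.
* **History.** The past-time integral is truncated at 5 time constants
  (25 ms, kernel < e^-5). Before the signal's first sample the channel is
  extended with its initial (resting) value, not zeros: the hair cell sat
  at rest before the stimulus, and zero-padding would inject a spurious
  step edge into the covariance.
* **Lag axis** 0–12.5 ms at the signal's sample resolution (pitches down to
  80 Hz); normalization by the lag-0 value; a window with no AC energy
  above the numerical cancellation floor degenerates to a delta at lag 0.

**Two readouts.** The time-resolved form `sacf`/`running_sacf` is evaluated
at single instants and is the right tool for tracking cues dynamically
(the animation exports). The *stimulus-level* form `stimulus_sacf` is the
infinite-time-constant limit: the whole-segment channel-summed
autocovariance, equivalently the running statistic accumulated over every
evaluation instant of the stimulus. Pitch decisions are read from the
stimulus-level form, for two reasons measured during development:

1. *Short-memory quasi-periodicity.* Within a 5-ms memory a slow 40-ms
   glide (e.g. 600→900 Hz) is locally almost periodic, so individual
   running frames necessarily show a secondary peak at the drifting
   instantaneous period — at salience comparable to a steady tone's. No
   per-frame criterion can call the tone "pitched" and the glide
   "unpitched". Integrated over the stimulus, the tone's peak accumulates
   at one lag while the glide's smears across its period range and
   collapses.
2. *Offset-ramp artifact.* Evaluated exactly at a tone's offset, the
   one-instant statistic weights the decaying ramp most heavily and the
   normalized peak heights creep slightly upward with lag, so the "largest"
   peak can land on a distant period multiple. The stimulus-level form
   decays with lag (finite-signal taper), making the first period peak the
   global one.

**Peak criteria.** "A peak at a non-zero lag" needs an operational
definition. Defaults, calibrated on the stimulus-level SACF of the
reference periphery: exclusion zone `lag_min` = 0.5 ms (clears the zero-lag
main lobe of the 300–3000 Hz band); `salience_threshold` = 0.87 and
`prominence` = 0.05 in normalized units. Under these, 150-ms tones from
300–1000 Hz qualify (their best-peak salience stays ≥ 0.95) while 40-ms
sweeps over ≥ a musical fifth (500→2000 Hz and 600→900 Hz, both directions)
do not (≤ 0.80). The margin is real but not enormous — a 40-ms narrowband
glide genuinely is *nearly* periodic, and these thresholds operationalize
the judgement that such residual humps are not pitch peaks. Peak ties
within `tie_tolerance` = 0.02 of the maximum salience resolve to the
shortest lag, the standard guard against period-multiple (octave) errors in
autocorrelation pitch models.

**Running pitch decision.** A running (frame-level) pitch is reported only
if qualifying per-frame peaks hold a consistent lag — within 2.5% of the
run median — for at least 10 ms of consecutive frames. A steady tone
sustains such a run for most of its duration; a sweep's frame peaks drift
~10–40% per 10 ms and never qualify. This stability requirement, rather
than per-frame absence, is the package's operational meaning of "the
running analysis produces no pitch estimate for FM sweeps" (see reason 1
above). Frame estimates shortly after stimulus onset can be distorted by
the hair-cell onset overshoot until the transient leaves the ~37.5-ms
correlation memory; the stability tests therefore start ≥ 75 ms into a
150-ms tone.

**Curvature.** The discrete second difference of the SACF versus lag, with
its sign-change lags, distinguishes "no peak at all" from "inflections
without a local maximum" — the narrowband sweep's SACF shows curvature sign
changes at non-zero lags even though no qualifying peak exists.

## Envelope / fine-structure asymmetry

For a single gammatone channel (by default the channel nearest the
geometric mean of the sweep band, ≈ 948.7 Hz for 500–2000 Hz), the analytic
signal gives envelope and fine structure. Because a down sweep is exactly
the time reverse of the up sweep, a *zero-phase* filter would respond with
mirror-image envelopes; the asymmetry report therefore compares the up
response with the **time-mirrored** down response, so all difference
statistics vanish for a zero-phase control and are nonzero exactly insofar
as the causal auditory filter is temporally asymmetric. Reported per
signal: envelope centroid time, terminal/initial envelope ratio (first vs.
last tenth), and a sliding-window fine-structure variance profile (5-ms
window, 1-ms hop — matching the pitch statistic's time constant). The
asymmetry analysis is filter-only (linear) by default; levels are not
calibrated, so these reproductions are structural, not trace-matched.
"Loudness cues" are represented only by envelope statistics — no loudness
model is included.

## Temporal-expectancy overlap

Geometry, measured from cue offset: expected onsets continue the cue's
period from the last cue tone's onset, so the k-th expected onset falls at
`duty·isi + (k−1)·isi`, k = 1..4 (for a 50%-duty 600-ms-ISI cue: 0.3, 0.9,
1.5, 2.1 s). The expectancy is either the onset instant or the full
on-period `[t_k, t_k + duty·isi]`. The target onset is uniform on
`[0, window − d]` with `window = 4·isi` and target duration `d` = 40 ms, so
the target always fits inside the four-cycle span; overlap is a
closed-interval intersection test. The exact probability is the measure of
the union of the favourable onset intervals `[t_k − d, end_k]` clipped to
the placement range, divided by the range — e.g. 0.16/2.36 ≈ 6.78% for
onset mode at 600-ms ISI, and (3·0.34 + 0.30)/2.36 ≈ 55.9% for the full
on-period mode (the fourth favourable interval is clipped by the window
end). The phase convention for the first expected onset does not affect the
probability as long as all four windows fit inside the placement range.

Trials per run is not externally constrained; the default of 100 makes the
per-run binomial spread wide enough that single runs reach the mid-teens in
onset mode (3·σ ≈ 7.5 points around a 6.8% mean), while 5000 runs pin the
grand mean to ±0.04 points. A single seeded generator (`numpy` PCG64) draws
all runs; identical seeds give identical results, and the simulated mean is
tested against the closed form at 3 standard errors.

## Problem sizes and numerical checks

The reference analyses are small by construction and run in seconds: the
overlap simulation is 5000 × 100 draws; the pitch pipeline processes
150–650-ms stimuli through 50 channels at 44.1 kHz. The test suite checks
the vectorized SACF against a literal nested-loop implementation of the
double sum on ≤ 5-channel, 50-ms instances at 8 kHz to 1e-9 relative, the
interval-union probability against a dense-grid numeric oracle, Parseval's
identity for the spectra, and exact log-spacing of the filterbank ladder to
1e-12 relative.

## Known limitations

* The peak criteria are calibrated operational definitions, not measured
  perceptual thresholds; the absolute salience scale depends on the
  hair-cell operating point (the global gain).
* The stimulus-level/running distinction matters: a sufficiently slow,
  sufficiently long glide would sustain a stable-lag run and be reported as
  pitched — the FM-null behaviour is a statement about *brief* sweeps.
* Presentation level is uncalibrated, so cochleagram grey levels and
  envelope magnitudes are comparable within this package only.
* Animations are exported as GIF (matplotlib PillowWriter); no MP4 encoder
  is assumed.
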