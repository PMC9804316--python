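"""Stimulus synthesis: sample-count arithmetic, phase conventions, presets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from pitchmodel import stimuli as st

SR = 44100.0


class TestPureTone:
    def test_sample_count_and_dominant_bin(self):
        w = st.make_pure_tone(500.0, 0.150, SR, 0.005)
        assert len(w) == 6615
        mag = np.abs(np.fft.rfft(w.samples))
        freqs = np.fft.rfftfreq(len(w), 1 / SR)
        assert freqs[np.argmax(mag)] == pytest.approx(500.0, abs=freqs[1])

    def test_unramped_tone_phase_and_rms(self):
        # integer number of cycles: first sample sin(0)=0, RMS exactly 1/sqrt(2)
        w = st.make_pure_tone(500.0, 0.150, SR, ramp=0.0)
        assert w.samples[0] == 0.0
        assert np.sqrt(np.mean(w.samples**2)) == pytest.approx(2**-0.5, rel=1e-12)

    def test_raw_autocorrelation_peaks_at_period(self):
        # direct autocorrelation oracle on the waveform itself
        w = st.make_pure_tone(500.0, 0.150, SR, 0.005)
        x = w.samples
        ac = np.correlate(x, x, "full")[x.size - 1 :]
        lo = int(0.001 * SR)  # skip the zero-lag lobe
        lag = (lo + np.argmax(ac[lo : int(0.003 * SR)])) / SR
        assert abs(lag - 0.002) <= 1.0 / SR

    @pytest.mark.parametrize(
        "freq,duration,ramp",
        [(23000.0, 0.1, 0.005), (500.0, -0.1, 0.0), (500.0, 0.01, 0.008), (-5.0, 0.1, 0.0)],
    )
    def test_invalid_arguments_rejected(self, freq, duration, ramp):
        with pytest.raises(ValueError):
            st.make_pure_tone(freq, duration, SR, ramp)


class TestLinearFM:
    def test_sample_count_and_midpoint_instantaneous_frequency(self):
        w = st.make_linear_fm(st.SweepSpec(500.0, 2000.0, 0.040, 0.005), SR)
        assert len(w) == 1764
        # phase-derivative oracle on the unramped sweep
        w2 = st.make_linear_fm(st.SweepSpec(500.0, 2000.0, 0.040, 0.0), SR)
        import scipy.signal

        phase = np.unwrap(np.angle(scipy.signal.hilbert(w2.samples)))
        inst = np.gradient(phase) * SR / (2 * np.pi)
        assert inst[int(0.020 * SR)] == pytest.approx(1250.0, rel=0.01)

    def test_degenerate_sweep_is_a_pure_tone(self):
        w = st.make_linear_fm(st.SweepSpec(700.0, 700.0, 0.1), SR)
        t = st.make_pure_tone(700.0, 0.1, SR)
        np.testing.assert_allclose(w.samples, t.samples, atol=1e-12)

    @pytest.mark.parametrize("band", [(500.0, 2000.0), (600.0, 900.0), (5500.0, 7000.0)])
    def test_down_sweep_is_time_reversed_up_sweep(self, band):
        f0, f1 = band
        up = st.make_linear_fm(st.SweepSpec(f0, f1, 0.040, 0.005), SR)
        down = st.make_linear_fm(st.SweepSpec(f1, f0, 0.040, 0.005), SR)
        scale = np.max(np.abs(up.samples))
        np.testing.assert_allclose(down.samples, up.samples[::-1], atol=1e-9 * scale)

    def test_edge_frequency_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            st.make_linear_fm(st.SweepSpec(500.0, 23000.0, 0.040), SR)

    def test_overlong_ramp_rejected(self):
        with pytest.raises(ValueError):
            st.SweepSpec(500.0, 2000.0, 0.008, 0.005)


class TestTonePair:
    def test_comparison_frequency_is_one_semitone_up(self, ):
        w = st.make_tone_pair(500.0, +1, 0.150, 0.350, SR)
        comparison = w.samples[int(0.5 * SR) :]
        mag = np.abs(np.fft.rfft(comparison))
        freqs = np.fft.rfftfreq(comparison.size, 1 / SR)
        assert freqs[np.argmax(mag)] == pytest.approx(500 * 2 ** (1 / 12), abs=freqs[1])

    def test_total_duration(self):
        w = st.make_tone_pair(500.0, +1, 0.150, 0.350, SR)
        assert w.duration == pytest.approx(0.650, abs=1 / SR)

    def test_zero_offset_zero_gap_is_contiguous_tone(self):
        w = st.make_tone_pair(500.0, 0, 0.150, 0.0, SR)
        assert len(w) == 2 * 6615
        assert np.max(np.abs(w.samples)) <= 1.0

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            st.make_tone_pair(500.0, 1, 0.15, -0.1, SR)


class TestRhythmicCue:
    def test_nominal_17hz_onsets_and_span(self):
        spec = st.RhythmicCueSpec.from_nominal_rate(1.7)
        assert spec.isi == pytest.approx(0.600)
        w, onsets = st.make_rhythmic_cue(spec, SR)
        assert onsets == pytest.approx([0.0, 0.6, 1.2, 1.8])
        assert spec.tone_duration == pytest.approx(0.300)
        assert w.duration == pytest.approx(2.1, abs=1 / SR)

    def test_2hz_arithmetic(self):
        spec = st.RhythmicCueSpec(rate=2.0)
        w, onsets = st.make_rhythmic_cue(spec, SR)
        assert onsets == pytest.approx([0.0, 0.5, 1.0, 1.5])
        assert spec.tone_duration == pytest.approx(0.250)

    def test_single_full_duty_cycle_is_continuous_tone(self):
        spec = st.RhythmicCueSpec(rate=2.0, n_cycles=1, duty=1.0)
        w, onsets = st.make_rhythmic_cue(spec, SR)
        assert onsets == [0.0]
        assert w.duration == pytest.approx(0.5, abs=1 / SR)
        # no internal silence
        mid = w.samples[int(0.01 * SR) : -int(0.01 * SR)]
        assert np.min(np.abs(mid).reshape(-1, 147).max(axis=1)) > 0.5

    def test_continuous_cue_duration_matches_rhythmic_span(self):
        spec = st.RhythmicCueSpec.from_nominal_rate(1.7)
        assert st.make_continuous_cue(spec, SR).duration == pytest.approx(2.1, abs=1 / SR)
        spec2 = st.RhythmicCueSpec(rate=2.0)
        assert st.make_continuous_cue(spec2, SR).duration == pytest.approx(1.75, abs=1 / SR)
        full = st.make_continuous_cue(spec2, SR, full_final_period=True)
        assert full.duration == pytest.approx(2.0, abs=1 / SR)

    def test_full_duty_continuous_equals_rhythmic_span(self):
        spec = st.RhythmicCueSpec(rate=2.0, duty=1.0)
        w, _ = st.make_rhythmic_cue(spec, SR)
        assert st.make_continuous_cue(spec, SR).duration == pytest.approx(w.duration)


class TestWavIO:
    def test_pcm16_roundtrip_within_quantization(self, tmp_path):
        w = st.make_pure_tone(500.0, 0.05, SR)
        path = tmp_path / "tone.wav"
        st.write_wav(w, path, "PCM_16")
        back = st.read_wav(path)
        assert back.sample_rate == SR
        assert np.max(np.abs(back.samples - w.samples)) <= 2**-15

    def test_float_roundtrip(self, tmp_path):
        w = st.make_linear_fm(st.SweepSpec(500, 2000, 0.040), SR)
        path = tmp_path / "sweep.wav"
        st.write_wav(w, path, "FLOAT")
        back = st.read_wav(path)
        np.testing.assert_allclose(back.samples, w.samples, atol=1e-7)

    def test_non_wav_bytes_rejected(self, tmp_path):
        path = tmp_path / "junk.wav"
        path.write_bytes(b"this is not audio")
        with pytest.raises(ValueError):
            st.read_wav(path)

    def test_audio_demo_s1_band_and_duration(self):
        w = st.audio_demo("S1", SR)
        spec = st.AUDIO_DEMOS["S1"]
        assert (spec.f_start, spec.f_end) == (5500.0, 7000.0)
        assert spec.duration == 0.040
        up = w.samples[: 1764]
        down = w.samples[-1764:]
        np.testing.assert_allclose(down, up[::-1], atol=1e-9)

    def test_unknown_demo_rejected(self):
        with pytest.raises(ValueError):
            st.audio_demo("S9")


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    freq=hst.floats(50.0, 5000.0),
    duration=hst.floats(0.02, 0.3),
    ramp=hst.floats(0.0, 0.01),
)
def test_tone_peak_and_length_invariants(freq, duration, ramp):
    """Every generated tone obeys peak <= 1 and exact sample-count arithmetic."""
    if 2 * ramp > duration:
        ramp = duration / 2
    w = st.make_pure_tone(freq, duration, SR, ramp)
    assert len(w) == round(duration * SR)
    assert np.max(np.abs(w.samples)) <= 1.0 + 1e-12


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    f0=hst.floats(300.0, 3000.0),
    ratio=hst.floats(1.1, 4.0),
    duration=hst.floats(0.02, 0.08),
)
def test_sweep_time_reversal_property(f0, ratio, duration):
    """Down sweep equals the time-reversed up sweep for any band and duration."""
    f1 = f0 * ratio
    up = st.make_linear_fm(st.SweepSpec(f0, f1, duration, 0.005), SR)
    down = st.make_linear_fm(st.SweepSpec(f1, f0, duration, 0.005), SR)
    np.testing.assert_allclose(down.samples, up.samples[::-1], atol=1e-9)


def test_semitone_ratio_constant():
    assert st.SEMITONE == pytest.approx(2 ** (1 / 12), rel=1e-15)
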