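"""Stimulus synthesis: calibration, timing, ramps, rove draws, WAV round-trip."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mocmask.stimuli import (P_REF, RoveSpec, ToneSpec, TrialSpec,
                             assemble_trial, draw_rove_level, export_wav,
                             make_tone)

FS = 100_000.0


class TestMakeTone:
    def test_sample_count_100ms_at_100khz(self):
        tone = make_tone(ToneSpec(4000.0, 0.100, 70.0, 0.002), FS)
        assert len(tone) == 10_000

    @pytest.mark.parametrize("level,expected_rms", [
        (0.0, 20e-6),
        (70.0, 20e-6 * 10 ** 3.5),  # ~0.0632 Pa
    ])
    def test_steady_rms_realizes_level(self, level, expected_rms):
        spec = ToneSpec(4000.0, 0.100, level, 0.002)
        tone = make_tone(spec, FS)
        steady = tone[300:9700]  # well inside the ramps
        rms = np.sqrt(np.mean(steady ** 2))
        assert rms == pytest.approx(expected_rms, rel=0.012)  # within 0.1 dB

    def test_low_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            make_tone(ToneSpec(4000.0, 0.01, 60.0, 0.001), 20_000.0)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ToneSpec(4000.0, -0.1, 60.0)
        with pytest.raises(ValueError):
            ToneSpec(4000.0, 0.01, 60.0, ramp_duration=0.02)
        with pytest.raises(ValueError):
            ToneSpec(0.0, 0.01, 60.0)

    @given(delta=st.sampled_from([20.0, 40.0]),
           level=st.floats(min_value=-10, max_value=60))
    @settings(max_examples=10, deadline=None)
    def test_20db_step_scales_rms_tenfold(self, delta, level):
        lo = make_tone(ToneSpec(4000.0, 0.05, level, 0.002), FS)
        hi = make_tone(ToneSpec(4000.0, 0.05, level + delta, 0.002), FS)
        ratio = np.sqrt(np.mean(hi ** 2) / np.mean(lo ** 2))
        assert ratio == pytest.approx(10.0 ** (delta / 20.0), rel=1e-9)


class TestAssembleTrial:
    def _spec(self, **kw):
        defaults = dict(
            masker=ToneSpec(4000.0, 0.200, 70.0, 0.002),
            probe=ToneSpec(4000.0, 0.010, 40.0, 0.005),
            delay=0.030, pre_silence=0.050, post_silence=0.050)
        defaults.update(kw)
        return TrialSpec(**defaults)

    def test_total_duration_is_sum_of_parts(self):
        stim = assemble_trial(self._spec(), FS)
        assert stim.duration == pytest.approx(0.340, abs=1e-6)

    def test_probe_absent_gives_silence_with_same_landmarks(self):
        present = assemble_trial(self._spec(), FS)
        absent = assemble_trial(self._spec(probe_present=False), FS)
        assert present.landmarks == absent.landmarks
        i0 = int(absent.landmarks["probe_onset"] * FS)
        i1 = int(absent.landmarks["probe_offset"] * FS)
        assert np.all(absent.samples[i0:i1] == 0.0)
        assert np.any(present.samples[i0:i1] != 0.0)

    def test_zero_delay_probe_onset_equals_masker_offset(self):
        stim = assemble_trial(self._spec(delay=0.0), FS)
        assert stim.landmarks["probe_onset"] == stim.landmarks["masker_offset"]

    def test_energy_zero_outside_sound_support(self):
        stim = assemble_trial(self._spec(), FS)
        pre = stim.samples[:int(stim.landmarks["masker_onset"] * FS)]
        post = stim.samples[int(stim.landmarks["probe_offset"] * FS) + 1:]
        assert np.all(pre == 0.0)
        assert np.all(post == 0.0)

    def test_negative_delay_rejected(self):
        with pytest.raises(ValueError):
            self._spec(delay=-0.01)


class TestRove:
    def test_draws_respect_truncation(self, rng):
        rove = RoveSpec(mean_level=70.0, sd=6.0, k=3.0)
        draws = [draw_rove_level(rove, rng) for _ in range(2000)]
        assert min(draws) >= 52.0 and max(draws) <= 88.0

    def test_zero_sd_is_constant(self, rng):
        assert draw_rove_level(RoveSpec(70.0, 0.0, 3.0), rng) == 70.0

    def test_sample_mean_matches_center(self):
        rng = np.random.default_rng(7)
        rove = RoveSpec(70.0, 6.0, 3.0)
        draws = np.array([draw_rove_level(rove, rng) for _ in range(100_000)])
        assert abs(draws.mean() - 70.0) < 0.1

    def test_fixed_seed_is_bit_reproducible(self):
        rove = RoveSpec(70.0, 6.0, 3.0)
        a = [draw_rove_level(rove, np.random.default_rng(3)) for _ in range(5)]
        b = [draw_rove_level(rove, np.random.default_rng(3)) for _ in range(5)]
        assert a == b


class TestExportWav:
    def test_round_trip_and_sidecar(self, tmp_path):
        spec = TrialSpec(probe=ToneSpec(4000.0, 0.010, 40.0, 0.002),
                         pre_silence=0.005, post_silence=0.005)
        stim = assemble_trial(spec, FS)
        path = export_wav(stim, tmp_path / "trial.wav")
        from scipy.io import wavfile
        sr, data = wavfile.read(path)
        meta = json.loads(path.with_suffix(".wav.json").read_text())
        assert sr == int(FS)
        restored = data.astype(np.float64) * meta["peak_pa"]
        assert np.allclose(restored, stim.samples, atol=1e-6)

    def test_empty_stimulus_rejected(self, tmp_path):
        spec = TrialSpec(probe=ToneSpec(4000.0, 0.010, 40.0, 0.002))
        stim = assemble_trial(spec, FS)
        stim.samples = np.array([])
        with pytest.raises(ValueError, match="zero-length"):
            export_wav(stim, tmp_path / "x.wav")
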