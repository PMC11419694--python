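"""Periphery contracts: filter calibration, HSR saturation, WDR growth,
gain-level equivalence, determinism."""

import numpy as np
import pytest

from mocmask.periphery import (HSR_DEFAULT, LSR_DEFAULT, PeripheryConfig,
                               PeripheryKernel, an_response, cochlear_filter,
                               ihc_transduce)
from mocmask.stimuli import ToneSpec, TrialSpec, assemble_trial, am_tone

FS = 100_000.0
CFG = PeripheryConfig()


def tone_stim(level, freq=4000.0, dur=0.2, ramp=0.01):
    spec = TrialSpec(probe=ToneSpec(freq, dur, level, ramp),
                     pre_silence=0.02, post_silence=0.05)
    return assemble_trial(spec, FS)


def steady_rate(resp, start=0.15, end=0.2):
    rfs = resp.sample_rate
    return float(np.mean(resp.rate[int(start * rfs):int(end * rfs)]))


class TestCochlearFilter:
    def test_on_cf_tone_has_unit_gain(self):
        stim = tone_stim(40.0)
        out = cochlear_filter(stim, None, CFG)
        seg = slice(int(0.1 * FS), int(0.2 * FS))
        gain_db = 10 * np.log10(np.mean(out[seg] ** 2) /
                                np.mean(stim.samples[seg] ** 2))
        assert abs(gain_db) < 0.5

    def test_off_frequency_masker_attenuated(self):
        on = cochlear_filter(tone_stim(70.0, freq=4000.0), None, CFG)
        off = cochlear_filter(tone_stim(70.0, freq=2400.0), None, CFG)
        seg = slice(int(0.1 * FS), int(0.2 * FS))
        rel_db = 10 * np.log10(np.mean(off[seg] ** 2) / np.mean(on[seg] ** 2))
        assert rel_db < -25.0  # tail path dominates, tens of dB down

    def test_fixed_gain_scales_low_level_output(self):
        stim = tone_stim(20.0)
        full = cochlear_filter(stim, 0.0, CFG)
        reduced = cochlear_filter(stim, -10.0, CFG)
        seg = slice(int(0.1 * FS), int(0.2 * FS))
        ratio_db = 10 * np.log10(np.mean(reduced[seg] ** 2) /
                                 np.mean(full[seg] ** 2))
        assert ratio_db == pytest.approx(-10.0, abs=0.5)

    def test_gain_outside_range_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            cochlear_filter(tone_stim(40.0), -CFG.gain_range - 5.0, CFG)


class TestIhc:
    def test_silence_rests_at_zero(self):
        out = ihc_transduce(np.zeros(5000), CFG, FS)
        assert np.allclose(out, 0.0)

    def test_compressive_at_high_level(self):
        x = np.sin(2 * np.pi * 4000.0 * np.arange(20000) / FS)
        lo = ihc_transduce(1.0 * x, CFG, FS)[5000:].mean()
        hi = ihc_transduce(2.0 * x, CFG, FS)[5000:].mean()
        assert hi < 2.0 * lo * 0.95

    def test_am_envelope_preserved(self):
        x = am_tone(4000.0, 64.0, 1.0, 0.5, 40.0, FS)
        kernel = PeripheryKernel(CFG, FS)
        env, _, _ = kernel.process_block(x, 0.0)
        seg = env[2000:] - env[2000:].mean()
        spec = np.abs(np.fft.rfft(seg))
        freqs = np.fft.rfftfreq(len(seg), 1.0 / CFG.rate_fs)
        peak = freqs[np.argmax(spec[(freqs > 10) & (freqs < 500)]) +
                     np.searchsorted(freqs, 10, side="right")]
        assert peak == pytest.approx(64.0, abs=2.0)


class TestFiberContracts:
    def test_hsr_steady_rates_at_40_and_70_within_10pct(self):
        r40 = steady_rate(an_response(tone_stim(40.0), None, CFG, "hsr"))
        r70 = steady_rate(an_response(tone_stim(70.0), None, CFG, "hsr"))
        assert abs(r70 - r40) / r40 < 0.10

    def test_hsr_saturation_slope_small_above_40(self):
        rates = [steady_rate(an_response(tone_stim(l), None, CFG, "hsr"))
                 for l in (45.0, 60.0, 75.0, 90.0)]
        slopes = np.diff(rates) / 15.0
        assert np.all(np.abs(slopes) < 1.0)  # sp/s per dB, ~flat

    def test_lsr_monotone_growth_over_wide_range(self):
        levels = np.arange(0.0, 91.0, 10.0)
        rates = [steady_rate(an_response(tone_stim(l), None, CFG, "lsr"))
                 for l in levels]
        assert np.all(np.diff(rates) >= -1e-9)
        r40 = rates[4]
        r70 = rates[7]
        assert r70 > 1.5 * r40  # clear margin at 70 vs 40 dB SPL

    def test_silence_gives_resting_rates(self):
        spec = TrialSpec(probe=ToneSpec(4000.0, 0.01, -200.0, 0.001),
                         pre_silence=0.3, post_silence=0.0, probe_present=False)
        stim = assemble_trial(spec, FS)
        hsr = an_response(stim, None, CFG, "hsr")
        lsr = an_response(stim, None, CFG, "lsr")
        expected_hsr = HSR_DEFAULT.q_steady(HSR_DEFAULT.spont) * HSR_DEFAULT.spont
        assert steady_rate(hsr, 0.2, 0.3) == pytest.approx(expected_hsr, rel=0.05)
        assert steady_rate(lsr, 0.2, 0.3) == pytest.approx(LSR_DEFAULT.spont, rel=0.05)

    def test_onset_emphasis_from_depletion(self):
        resp = an_response(tone_stim(40.0), None, CFG, "hsr")
        rfs = resp.sample_rate
        onset = resp.rate[int(0.02 * rfs):int(0.06 * rfs)].max()
        steady = steady_rate(resp)
        assert onset > 1.5 * steady

    def test_gain_level_equivalence_for_low_level_tones(self):
        # a g-dB gain reduction shifts the effective level by about -g dB
        shifted = steady_rate(an_response(tone_stim(30.0), None, CFG, "hsr"))
        reduced = steady_rate(an_response(tone_stim(40.0), -10.0, CFG, "hsr"))
        assert reduced == pytest.approx(shifted, rel=0.06)

    def test_identical_config_is_deterministic(self):
        stim = tone_stim(50.0)
        a = an_response(stim, None, CFG, "hsr").rate
        b = an_response(stim, None, CFG, "hsr").rate
        assert np.array_equal(a, b)

    def test_block_processing_matches_single_pass(self):
        stim = tone_stim(50.0)
        single = PeripheryKernel(CFG, FS)
        _, hsr_one, _ = single.process_block(stim.samples, 0.0)
        blocked = PeripheryKernel(CFG, FS)
        parts = [blocked.process_block(chunk, 0.0)[1]
                 for chunk in np.array_split(stim.samples, 97)]
        assert np.array_equal(hsr_one, np.concatenate(parts))
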