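"""2IFC harness: window placement, decision symmetry, logistic-fit recovery."""

import numpy as np
import pytest
from scipy.special import expit

from mocmask.periphery import RateResponse
from mocmask.psychoacoustics import (DecisionConfig, DecisionWindow,
                                     PsychometricData, criterion_offset,
                                     fit_threshold, make_window,
                                     trial_decision)
from mocmask.stimuli import ToneSpec, TrialSpec

RFS = 10_000.0


def delay_trial(delay, pre=0.05, post=0.3):
    return TrialSpec(masker=ToneSpec(4000.0, 0.2, 40.0, 0.01),
                     probe=ToneSpec(4000.0, 0.02, 40.0, 0.01),
                     delay=delay, pre_silence=pre, post_silence=post)


class TestWindows:
    def test_physiological_window_follows_probe_onset(self):
        # probe onset at 252.83 ms -> window 257.83-297.83 ms
        spec = TrialSpec(masker=ToneSpec(4000.0, 0.2, 40.0, 0.01),
                         probe=ToneSpec(4000.0, 0.02, 40.0, 0.01),
                         delay=0.00283, pre_silence=0.05, post_silence=0.3)
        w = make_window("physiological", spec)
        assert w.start == pytest.approx(0.25783, abs=1e-6)
        assert w.end == pytest.approx(0.29783, abs=1e-6)

    def test_physiological_window_shifts_with_delay(self):
        w0 = make_window("physiological", delay_trial(0.0))
        w150 = make_window("physiological", delay_trial(0.15))
        assert w150.start - w0.start == pytest.approx(0.15, abs=1e-9)

    @pytest.mark.parametrize("delay", [0.0, 0.03])
    def test_psychophysical_window_fixed(self, delay):
        w = make_window("psychophysical", delay_trial(delay))
        assert (w.start, w.end) == (0.150, 0.300)

    def test_short_stimulus_warns(self):
        spec = delay_trial(0.15, post=0.0)
        with pytest.warns(UserWarning, match="post_silence"):
            make_window("physiological", spec)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            DecisionWindow("physiological", 0.2, 0.1)


def flat_response(rate, n=3000, peak=None, peak_at=None):
    r = np.full(n, float(rate))
    if peak is not None:
        i = int(peak_at * RFS)
        r[i:i + 50] = peak
    return RateResponse("HSR", r, RFS, {})


class TestTrialDecision:
    WINDOW = DecisionWindow("physiological", 0.1, 0.14)

    def test_clear_difference_is_always_correct(self, rng):
        target = flat_response(50.0, peak=400.0, peak_at=0.11)
        standard = flat_response(50.0)
        cfg = DecisionConfig(noise="poisson", n_fibers=40)
        results = [trial_decision(target, standard, self.WINDOW, rng, cfg)
                   for _ in range(50)]
        assert np.mean(results) > 0.95

    def test_identical_intervals_give_chance(self, rng):
        resp = flat_response(60.0)
        cfg = DecisionConfig(noise="poisson", n_fibers=10)
        results = [trial_decision(resp, resp, self.WINDOW, rng, cfg)
                   for _ in range(2000)]
        assert np.mean(results) == pytest.approx(0.5, abs=0.04)

    def test_pc_nondecreasing_in_signal_strength(self, rng):
        cfg = DecisionConfig(noise="poisson", n_fibers=10)
        standard = flat_response(60.0)
        pcs = []
        for peak in (60.0, 120.0, 240.0, 480.0):
            target = flat_response(60.0, peak=peak, peak_at=0.11)
            hits = [trial_decision(target, standard, self.WINDOW, rng, cfg)
                    for _ in range(400)]
            pcs.append(np.mean(hits))
        assert np.all(np.diff(pcs) > -0.05)

    def test_gaussian_noise_variant_behaves(self, rng):
        cfg = DecisionConfig(noise="gaussian", gaussian_sd=20.0)
        target = flat_response(50.0, peak=200.0, peak_at=0.11)
        standard = flat_response(50.0)
        hits = [trial_decision(target, standard, self.WINDOW, rng, cfg)
                for _ in range(200)]
        assert np.mean(hits) > 0.9


def synthetic_psychometric(rng, midpoint, slope=4.0, n_per_level=1000,
                           levels=None):
    levels = np.asarray(levels if levels is not None
                        else np.arange(midpoint - 20, midpoint + 21, 5.0))
    p = 0.5 + 0.5 * expit((levels - midpoint) / slope)
    correct = rng.binomial(n_per_level, p)
    return PsychometricData(levels=levels,
                            n_trials=np.full(len(levels), n_per_level),
                            n_correct=correct)


class TestFitThreshold:
    def test_recovers_known_midpoint_within_1db(self, rng):
        data = synthetic_psychometric(rng, midpoint=40.0)
        est = fit_threshold(data, criterion=0.707)
        expected = 40.0 + 4.0 * criterion_offset(0.707)
        assert est.converged
        assert est.threshold == pytest.approx(expected, abs=1.0)

    def test_recovery_bias_below_half_db_across_midpoints(self):
        # parameter-recovery contract on synthetic Bernoulli data
        for midpoint in (10.0, 35.0, 60.0):
            errors = []
            for rep in range(8):
                rng = np.random.default_rng(1000 + int(midpoint) * 10 + rep)
                data = synthetic_psychometric(rng, midpoint=midpoint)
                est = fit_threshold(data, criterion=0.707)
                expected = midpoint + 4.0 * criterion_offset(0.707)
                errors.append(est.threshold - expected)
            assert abs(np.mean(errors)) < 0.5

    def test_chance_data_flagged_unconverged(self, rng):
        levels = np.arange(0.0, 41.0, 5.0)
        data = PsychometricData(
            levels=levels, n_trials=np.full(len(levels), 100),
            n_correct=rng.binomial(100, 0.5, len(levels)))
        est = fit_threshold(data, criterion=0.707)
        assert not est.converged

    def test_lower_criterion_gives_lower_threshold(self, rng):
        data = synthetic_psychometric(rng, midpoint=40.0)
        th61 = fit_threshold(data, criterion=0.61).threshold
        th707 = fit_threshold(data, criterion=0.707).threshold
        assert th61 < th707

    def test_criterion_bounds_enforced(self, rng):
        data = synthetic_psychometric(rng, midpoint=40.0)
        with pytest.raises(ValueError):
            fit_threshold(data, criterion=0.4)

    def test_tally_invariants_enforced(self):
        with pytest.raises(ValueError):
            PsychometricData(levels=np.array([0.0, 5.0]),
                             n_trials=np.array([10, 10]),
                             n_correct=np.array([11, 5]))
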