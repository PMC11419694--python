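"""Two-interval forced-choice harness and psychometric threshold estimation.

The model's rate responses are deterministic; trial-to-trial variability is
injected at the decision stage.  By default each interval's decision variable
is the maximum spike count in a sliding 5 ms sub-window within the decision
window, with spikes drawn from an inhomogeneous Poisson process over a small
pool of statistically independent fibers.  An additive-Gaussian internal-noise
alternative (max of the windowed rate plus noise) is available behind the same
interface, as is a mean-rate (total count) decision statistic used for
contrast analyses.

Two decision-window conventions:

* physiological — 40 ms, starting 5 ms after probe onset, shifted with the
  masker-probe delay (matches spike-counting windows in single-unit studies);
* psychophysical — fixed 150-300 ms re stimulus start, never shifted,
  reflecting listeners' weaker a priori knowledge of the probe time.

Percent correct is tabulated per probe level and a logistic psychometric
function with chance asymptote 0.5 is fitted by maximum likelihood; the
threshold is the level where the fit crosses the criterion (0.61 or 0.707).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .periphery import RateResponse
from .stimuli import RoveSpec, TrialSpec, draw_rove_level

__all__ = [
    "DecisionWindow", "DecisionConfig", "PsychometricData", "ThresholdEstimate",
    "make_window", "decision_variable", "trial_decision", "run_2ifc",
    "fit_threshold", "criterion_offset",
]


@dataclass(frozen=True)
class DecisionWindow:
    mode: str  # "physiological" | "psychophysical"
    start: float  # s, re stimulus start
    end: float

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("window end must exceed start")


#: Fixed psychophysical window (s re stimulus start).
PSYCHOPHYSICAL_WINDOW = (0.150, 0.300)
#: Physiological window: starts this long after probe onset, with this length.
PHYSIOLOGICAL_OFFSET = 0.005
PHYSIOLOGICAL_LENGTH = 0.040


def make_window(mode: str, trial_spec: TrialSpec) -> DecisionWindow:
    """Build the decision window for a trial.

    The physiological window tracks the probe onset (it shifts with the
    masker-probe delay); the psychophysical window is fixed re stimulus start.
    """
    if mode == "physiological":
        start = trial_spec.probe_onset + PHYSIOLOGICAL_OFFSET
        end = start + PHYSIOLOGICAL_LENGTH
    elif mode == "psychophysical":
        start, end = PSYCHOPHYSICAL_WINDOW
    else:
        raise ValueError(f"unknown window mode {mode!r}")
    if end > trial_spec.total_duration + 1e-9:
        warnings.warn(
            f"decision window [{start:.3f}, {end:.3f}] s extends past the stimulus "
            f"({trial_spec.total_duration:.3f} s); increase post_silence",
            stacklevel=2,
        )
    return DecisionWindow(mode=mode, start=start, end=end)


@dataclass(frozen=True)
class DecisionConfig:
    """How a deterministic rate becomes a stochastic per-interval decision variable.

    Three noise placements:

    * ``input`` (default) — Gaussian rate noise is injected at the auditory
      nerve and propagated through whatever stage feeds the decision (for the
      IC, through the SFIE model), emulating the stochasticity of AN firing.
      The noise has a fast (white) and a slow (low-passed, excitability-drift)
      component, a two-band stand-in for the low-frequency-heavy variability
      of AN discharge rates; the slow component dominates the window-max
      statistic at the AN, while the SFIE stage's modulation bandpass largely
      rejects it, so the fast component sets the IC noise floor.  The decision
      variable is computed directly from the realized rate.
    * ``poisson`` — the stage's deterministic rate drives an inhomogeneous
      Poisson spike count over a small pool of independent fibers.
    * ``gaussian`` — additive internal noise on the windowed rate statistic.
    """

    noise: str = "input"  # "input" | "poisson" | "gaussian"
    statistic: str = "max"  # "max" (sliding sub-window) | "mean" (whole window)
    an_sigma_fast: float = 7.5  # sp/s, white rate noise at the AN (input mode)
    an_sigma_slow: float = 13.0  # sp/s, slow drift noise at the AN (input mode)
    slow_cutoff: float = 1.5  # Hz, one-pole cutoff of the drift component
    n_fibers: int = 40  # independent Poisson fibers pooled
    subwindow: float = 0.005  # s, sliding sub-window for the max statistic
    gaussian_sd: float = 10.0  # sp/s, internal noise for the gaussian model

    def __post_init__(self) -> None:
        if self.noise not in ("input", "poisson", "gaussian"):
            raise ValueError("noise must be 'input', 'poisson' or 'gaussian'")
        if self.statistic not in ("max", "mean"):
            raise ValueError("statistic must be 'max' or 'mean'")


def _window_rate(resp: RateResponse, window: DecisionWindow) -> np.ndarray:
    seg = resp.window_slice(window.start, window.end)
    if len(seg) == 0:
        raise ValueError("decision window lies outside the response")
    return seg


def decision_variable(resp: RateResponse, window: DecisionWindow,
                      rng: np.random.Generator, cfg: DecisionConfig) -> float:
    """One stochastic realization of the interval's decision variable."""
    seg = _window_rate(resp, window)
    dt = 1.0 / resp.sample_rate
    if cfg.noise == "input":
        # noise already realized in the rate trace; smooth over the sub-window
        if cfg.statistic == "mean":
            return float(np.mean(seg))
        w = max(int(round(cfg.subwindow * resp.sample_rate)), 1)
        if len(seg) <= w:
            return float(np.mean(seg))
        return float(np.convolve(seg, np.ones(w) / w, mode="valid").max())
    if cfg.noise == "poisson":
        counts = rng.poisson(np.maximum(seg, 0.0) * dt * cfg.n_fibers)
        if cfg.statistic == "mean":
            return float(counts.sum())
        w = max(int(round(cfg.subwindow * resp.sample_rate)), 1)
        if len(counts) <= w:
            return float(counts.sum())
        sliding = np.convolve(counts, np.ones(w, dtype=int), mode="valid")
        return float(sliding.max())
    # gaussian internal noise on the rate statistic itself
    if cfg.statistic == "mean":
        stat = float(np.mean(seg))
    else:
        w = max(int(round(cfg.subwindow * resp.sample_rate)), 1)
        if len(seg) <= w:
            stat = float(np.mean(seg))
        else:
            stat = float(np.convolve(seg, np.ones(w) / w, mode="valid").max())
    return stat + float(rng.normal(0.0, cfg.gaussian_sd))


def trial_decision(resp_target: RateResponse, resp_standard: RateResponse,
                   window: DecisionWindow, rng: np.random.Generator,
                   cfg: DecisionConfig = DecisionConfig()) -> bool:
    """Pick the interval with the larger decision variable; ties by fair coin."""
    dv_t = decision_variable(resp_target, window, rng, cfg)
    dv_s = decision_variable(resp_standard, window, rng, cfg)
    if dv_t == dv_s:
        return bool(rng.random() < 0.5)
    return dv_t > dv_s


@dataclass
class PsychometricData:
    """Per-level 2IFC trial tallies."""

    levels: np.ndarray  # probe levels, dB SPL
    n_trials: np.ndarray
    n_correct: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.n_trials = np.asarray(self.n_trials, dtype=int)
        self.n_correct = np.asarray(self.n_correct, dtype=int)
        if np.any(self.n_correct > self.n_trials) or np.any(self.n_correct < 0):
            raise ValueError("0 <= correct <= trials must hold at every level")
        if len(self.levels) < 2:
            raise ValueError("need at least two probe levels")

    @property
    def proportion_correct(self) -> np.ndarray:
        return self.n_correct / np.maximum(self.n_trials, 1)


@dataclass
class ThresholdEstimate:
    threshold: float  # dB SPL
    criterion: float
    midpoint: float
    slope: float
    converged: bool
    in_range: bool
    data: Optional[PsychometricData] = None


def run_2ifc(model: Callable[..., RateResponse],
             trial_template: TrialSpec,
             probe_levels: Sequence[float],
             n_trials: int,
             mode: str,
             rng: np.random.Generator,
             rove: Optional[RoveSpec] = None,
             decision: DecisionConfig = DecisionConfig(),
             level_quantum: float = 0.0,
             ) -> Tuple[PsychometricData, list]:
    """Simulate the 2IFC method-of-constant-stimuli task.

    ``model(spec, rng, decision)`` maps a TrialSpec to the decision-stage
    RateResponse (a stochastic realization in the input-noise mode) and should
    cache the deterministic part internally: only the noise draws differ
    across trials.  In rove mode each interval's
    masker level is drawn independently (optionally quantized to
    ``level_quantum`` dB so the deterministic response cache stays small).

    Returns the tallies plus a per-trial log of
    (level, correct, target_masker_level, standard_masker_level) for the
    rove-correlation analysis.
    """
    levels = np.asarray(probe_levels, dtype=float)
    n_correct = np.zeros(len(levels), dtype=int)
    log: list = []
    window = make_window(mode, trial_template)
    for i, level in enumerate(levels):
        for _ in range(n_trials):
            if rove is not None:
                lm_t = draw_rove_level(rove, rng)
                lm_s = draw_rove_level(rove, rng)
                if level_quantum > 0:
                    lm_t = round(lm_t / level_quantum) * level_quantum
                    lm_s = round(lm_s / level_quantum) * level_quantum
                target_spec = trial_template.with_masker_level(lm_t).with_probe_level(level)
                standard_spec = trial_template.with_masker_level(lm_s).with_probe_level(level)
            else:
                lm_t = lm_s = (trial_template.masker.level
                               if trial_template.masker is not None else np.nan)
                target_spec = trial_template.with_probe_level(level)
                standard_spec = target_spec
            target_spec = replace(target_spec, probe_present=True)
            standard_spec = replace(standard_spec, probe_present=False)
            resp_t = model(target_spec, rng, decision)
            resp_s = model(standard_spec, rng, decision)
            correct = trial_decision(resp_t, resp_s, window, rng, decision)
            n_correct[i] += correct
            log.append((float(level), bool(correct), float(lm_t), float(lm_s)))
    data = PsychometricData(levels=levels,
                            n_trials=np.full(len(levels), n_trials),
                            n_correct=n_correct,
                            meta={"mode": mode, "rove": rove is not None})
    return data, log


def criterion_offset(criterion: float) -> float:
    """Offset (in slope units) from the logistic midpoint to the criterion level."""
    q = 2.0 * criterion - 1.0
    return float(np.log(q / (1.0 - q)))


def fit_threshold(data: PsychometricData, criterion: float = 0.707) -> ThresholdEstimate:
    """ML logistic fit P(c) = 0.5 + 0.5*expit((L - m)/s); threshold at the criterion.

    The lower asymptote is chance (0.5) and the upper asymptote 1 (no lapse
    term).  The estimate is flagged unconverged when the optimizer fails or
    the observed proportions never span the criterion.
    """
    if not 0.5 < criterion < 1.0:
        raise ValueError("criterion must lie in (0.5, 1)")
    levels, n, k = data.levels, data.n_trials, data.n_correct

    def nll(params: np.ndarray) -> float:
        m, log_s = params
        s = np.exp(log_s)
        p = 0.5 + 0.5 * expit((levels - m) / s)
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return float(-(k * np.log(p) + (n - k) * np.log(1.0 - p)).sum())

    pc = data.proportion_correct
    above = levels[pc >= criterion]
    m0 = float(above.min()) if len(above) else float(levels.mean())
    best = None
    for s0 in (2.0, 5.0, 10.0):
        res = minimize(nll, x0=np.array([m0, np.log(s0)]), method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    m_hat, s_hat = float(best.x[0]), float(np.exp(best.x[1]))
    threshold = m_hat + s_hat * criterion_offset(criterion)
    spans = bool(pc.max() >= criterion >= pc.min())
    converged = bool(best.success) and spans
    in_range = bool(levels.min() <= threshold <= levels.max())
    return ThresholdEstimate(threshold=threshold, criterion=criterion,
                             midpoint=m_hat, slope=s_hat,
                             converged=converged, in_range=in_range, data=data)
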