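"""MOC efferent feedback: rate-driven cochlear-gain dynamics and the closed loop.

The medial-olivocochlear stage receives two inputs: the wide-dynamic-range
(WDR) rate carried by an LSR auditory-nerve fiber, and a fluctuation-driven
rate from a bandpass modulation-filter IC model.  Rectified-above-spontaneous
drive from both is mapped linearly to a target gain reduction, and the gain
follows that target with first-order low-pass dynamics, clipped to
[gain_floor, 0] dB.  Tone maskers engage the loop almost entirely through the
WDR path; the IC path matters only for fluctuating inputs.

``run_closed_loop`` advances periphery, feedback IC and gain block-by-block
(gain held constant within a block), then computes the final SFIE IC response
from the HSR trace.  With the loop disabled the gain stays at 0 dB and the
result is numerically identical to the open-loop no-efferent model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .midbrain import ModFilterConfig, SfieConfig, ModFilterState, sfie_ic
from .periphery import PeripheryConfig, PeripheryKernel, RateResponse
from .stimuli import Stimulus

__all__ = ["MocConfig", "GainTrajectory", "ClosedLoopResult", "update_gain",
           "run_closed_loop"]


@dataclass(frozen=True)
class MocConfig:
    wdr_weight: float = 0.53  # dB of gain reduction per (sp/s) of WDR drive
    ic_weight: float = 0.05  # same units, fluctuation path
    tau: float = 0.08  # time constant while gain reduction deepens, s
    tau_decay: Optional[float] = None  # recovery time constant; None -> tau
    gain_floor: Optional[float] = None  # dB; None -> -periphery.gain_range
    enabled: bool = True
    block_dur: float = 0.001  # loop update granularity, s

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError("tau must be positive")
        if self.tau_decay is not None and not self.tau_decay > 0:
            raise ValueError("tau_decay must be positive")
        if self.wdr_weight < 0 or self.ic_weight < 0:
            raise ValueError("weights must be non-negative")
        if not self.block_dur > 0:
            raise ValueError("block_dur must be positive")


@dataclass
class GainTrajectory:
    """Cochlear gain reduction (dB <= 0) vs time."""

    gain: np.ndarray
    sample_rate: float

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.gain)) / self.sample_rate

    def at_audio_rate(self, n: int, fs: float) -> np.ndarray:
        t = np.arange(n) / fs
        return np.interp(t, self.time, self.gain)


@dataclass
class ClosedLoopResult:
    stimulus: Stimulus
    hsr: RateResponse
    wdr: RateResponse
    gain: GainTrajectory
    ic_feedback: RateResponse
    ic_sfie: RateResponse
    meta: dict = field(default_factory=dict)


def update_gain(wdr: RateResponse, ic: RateResponse, moc: MocConfig,
                wdr_spont: float = 1.0, ic_spont: float = 0.0,
                gain_floor: float = -40.0) -> GainTrajectory:
    """Open-loop gain dynamics for given (fixed) rate inputs.

    Useful for analyzing the dynamics in isolation; the closed loop uses the
    same first-order update driven by the evolving rates.
    """
    floor = moc.gain_floor if moc.gain_floor is not None else gain_floor
    fs = wdr.sample_rate
    drive = (moc.wdr_weight * np.maximum(wdr.rate - wdr_spont, 0.0)
             + moc.ic_weight * np.maximum(ic.rate - ic_spont, 0.0))
    target = np.clip(-drive, floor, 0.0)
    g = np.empty_like(target)
    state = 0.0
    tau_dec = moc.tau_decay if moc.tau_decay is not None else moc.tau
    c_down = 1.0 - np.exp(-1.0 / (fs * moc.tau))
    c_up = 1.0 - np.exp(-1.0 / (fs * tau_dec))
    for i, tg in enumerate(target):
        state += (tg - state) * (c_down if tg < state else c_up)
        g[i] = state
    return GainTrajectory(gain=np.clip(g, floor, 0.0), sample_rate=fs)


def run_closed_loop(stimulus: Stimulus, periphery_config: PeripheryConfig,
                    moc_config: MocConfig, sfie_config: SfieConfig,
                    modfilter_config: Optional[ModFilterConfig] = None
                    ) -> ClosedLoopResult:
    """Simulate all five stages with block-wise gain feedback."""
    modfilter_config = modfilter_config or ModFilterConfig()
    floor = (moc_config.gain_floor if moc_config.gain_floor is not None
             else -periphery_config.gain_range)
    fs = stimulus.sample_rate
    kernel = PeripheryKernel(periphery_config, fs)
    modfilt = ModFilterState(modfilter_config, periphery_config.rate_fs)

    block = int(round(moc_config.block_dur * fs))
    n = len(stimulus.samples)
    n_blocks = int(np.ceil(n / block))

    hsr_parts, lsr_parts, icfb_parts = [], [], []
    gain_track = np.zeros(n_blocks)
    lsr_spont = periphery_config.lsr.spont
    g = 0.0
    tau_dec = (moc_config.tau_decay if moc_config.tau_decay is not None
               else moc_config.tau)
    coeff_down = 1.0 - np.exp(-moc_config.block_dur / moc_config.tau)
    coeff_up = 1.0 - np.exp(-moc_config.block_dur / tau_dec)

    for ib in range(n_blocks):
        xb = stimulus.samples[ib * block:(ib + 1) * block]
        _, hsr_b, lsr_b = kernel.process_block(xb, g)
        icfb_b = modfilt.process(hsr_b)
        hsr_parts.append(hsr_b)
        lsr_parts.append(lsr_b)
        icfb_parts.append(icfb_b)
        gain_track[ib] = g
        if moc_config.enabled and len(lsr_b):
            drive = (moc_config.wdr_weight * np.mean(np.maximum(lsr_b - lsr_spont, 0.0))
                     + moc_config.ic_weight * np.mean(icfb_b))
            target = float(np.clip(-drive, floor, 0.0))
            g += (target - g) * (coeff_down if target < g else coeff_up)
            g = float(np.clip(g, floor, 0.0))

    _check_stability(gain_track, floor)

    lm = dict(stimulus.landmarks)
    rfs = periphery_config.rate_fs
    hsr = RateResponse("HSR", np.concatenate(hsr_parts), rfs, lm)
    wdr = RateResponse("WDR", np.concatenate(lsr_parts), rfs, lm)
    icfb = RateResponse("IC_feedback", np.concatenate(icfb_parts), rfs, lm)
    gain = GainTrajectory(gain=gain_track, sample_rate=1.0 / moc_config.block_dur)
    ic = sfie_ic(hsr, sfie_config)
    return ClosedLoopResult(stimulus=stimulus, hsr=hsr, wdr=wdr, gain=gain,
                            ic_feedback=icfb, ic_sfie=ic,
                            meta={"efferents": moc_config.enabled})


def _check_stability(gain_track: np.ndarray, floor: float) -> None:
    """Flag sustained large-amplitude gain oscillation as a diagnostic failure."""
    if len(gain_track) < 4:
        return
    dg = np.diff(gain_track)
    flips = (dg[1:] * dg[:-1] < 0) & (np.abs(dg[1:]) > 0.25 * abs(floor))
    if np.count_nonzero(flips) > 10:
        raise RuntimeError(
            "efferent loop unstable: gain oscillates with large amplitude; "
            "reduce weights or increase tau/block_dur"
        )
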