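"""Phenomenological auditory-nerve periphery at a single 4 kHz channel.

The chain is: level-dependent cochlear filter (sharp "tip" whose gain the MOC
efferents can reduce, plus a fixed low-gain "tail" that is not under efferent
control) -> inner-hair-cell transduction (rectify, saturate, low-pass) ->
adapting synapse producing instantaneous firing rate for a high-spontaneous-
rate (HSR) and a low-spontaneous-rate / wide-dynamic-range (LSR) fiber.

The stage is deliberately minimal: it is governed by behavioral contracts
(HSR rate-level saturating at or below 40 dB SPL, LSR monotone growth over at
least 0-80 dB SPL, human-like frequency selectivity, near-0 dB SPL detection
thresholds downstream) rather than by a biophysical cochlear model.  All
stochasticity lives in the decision stage; this module is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .stimuli import P_REF, Stimulus

__all__ = [
    "FiberParams",
    "PeripheryConfig",
    "RateResponse",
    "PeripheryKernel",
    "cochlear_filter",
    "ihc_transduce",
    "synapse_rate",
    "an_response",
]


@dataclass(frozen=True)
class FiberParams:
    """Steady-state rate-level sigmoid plus single-store adaptation.

    The static (undepleted) rate is ``spont + (sat - spont) * expit((L -
    midpoint)/slope)`` with L the effective level (dB SPL) at the channel.
    Adaptation is depletion-style: a releasable resource ``q`` in [0, 1]
    recovers with time constant ``adapt_tau`` and is consumed in proportion
    to the emitted rate,

        dq/dt = (1 - q)/adapt_tau - q * r_static / depletion_capacity,

    and the output rate is ``q * r_static``.  The onset response to a tone
    from silence is (nearly) the full static rate; the steady-state rate is
    scaled by ``q_ss = 1 / (1 + adapt_tau * r_static / capacity)``; and the
    response to a probe shortly after a masker is multiplicatively reduced by
    the still-depleted ``q`` -- the synaptic component of forward masking.
    Set ``depletion_capacity`` to ``inf`` for a non-adapting fiber.
    """

    spont: float  # spontaneous rate, sp/s (undepleted)
    sat: float  # saturation rate, sp/s
    midpoint: float  # rate-level sigmoid midpoint, dB SPL
    slope: float  # sigmoid slope parameter, dB
    adapt_tau: float = 0.08  # resource recovery time constant, s
    depletion_capacity: float = 10.0  # resource turnover scale, spikes
    sloping_rate: float = 0.0  # sp/s per dB above sloping_knee: sloping saturation
    sloping_knee: float = 60.0  # dB SPL where the sloping component begins

    def q_steady(self, static_rate: float) -> float:
        """Steady-state resource level at a given static rate."""
        return 1.0 / (1.0 + self.adapt_tau * static_rate / self.depletion_capacity)


#: HSR fiber: high spont, narrow dynamic range, saturated by ~40 dB SPL up to
#: a shallow sloping-saturation component.
HSR_DEFAULT = FiberParams(spont=60.0, sat=250.0, midpoint=23.0, slope=9.0,
                          adapt_tau=0.08, depletion_capacity=14.0,
                          sloping_rate=1.5, sloping_knee=60.0)
#: LSR fiber (the wide-dynamic-range MOC input): low spont, shallow growth,
#: non-adapting so the efferent drive tracks the masker level.
LSR_DEFAULT = FiberParams(spont=1.0, sat=120.0, midpoint=45.0, slope=12.0,
                          depletion_capacity=float("inf"))


@dataclass(frozen=True)
class PeripheryConfig:
    cf: float = 4000.0  # characteristic frequency, Hz
    q_erb: float = 19.2  # human sharpness, cf / ERB
    gain_range: float = 40.0  # max cochlear-amplifier gain removable by MOC, dB
    tail_attenuation_db: float = 35.0  # fixed tail gain re tip peak, dB
    tail_bandwidth: float = 2500.0  # tail resonance decay parameter, Hz
    ihc_sat: float = 0.2  # IHC saturation knee, Pa
    ihc_cutoff: float = 2500.0  # IHC low-pass cutoff, Hz
    rate_fs: float = 10000.0  # sampling rate of rate responses, Hz
    hsr: FiberParams = HSR_DEFAULT
    lsr: FiberParams = LSR_DEFAULT

    def __post_init__(self) -> None:
        if not self.cf > 0:
            raise ValueError("cf must be positive")
        if self.gain_range < 0:
            raise ValueError("gain_range must be non-negative")


@dataclass
class RateResponse:
    """Instantaneous firing rate (sp/s) of one model stage vs time."""

    stage: str  # HSR | WDR | IC_feedback | IC_SFIE
    rate: np.ndarray
    sample_rate: float
    landmarks: dict = field(default_factory=dict)

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.rate)) / self.sample_rate

    def window_slice(self, start: float, end: float) -> np.ndarray:
        i0 = max(int(round(start * self.sample_rate)), 0)
        i1 = min(int(round(end * self.sample_rate)), len(self.rate))
        return self.rate[i0:i1]


def _complex_resonator_coeffs(cf: float, decay_bw: float, order: int, fs: float):
    """Cascaded complex one-pole resonator: impulse response ~ t^(n-1) e^(-2 pi b t) e^(j 2 pi cf t).

    Returns (b, a) normalized so the amplitude response of 2*Re(.) at ``cf``
    is unity.
    """
    pole = np.exp((-2.0 * np.pi * decay_bw + 2.0j * np.pi * cf) / fs)
    a = np.poly([pole] * order)
    w0 = 2.0 * np.pi * cf / fs
    # H(e^jw) = 1 / sum_k a_k e^-jkw; amplitude through 2*Re(.) for a real
    # sinusoid at cf is |H(cf)|
    denom = np.polyval(a[::-1], np.exp(-1j * w0))
    b = np.array([abs(denom)], dtype=complex)
    return b, a


def _onepole_lowpass_coeffs(cutoff: float, order: int, fs: float):
    alpha = np.exp(-2.0 * np.pi * cutoff / fs)
    a = np.poly([alpha] * order)
    b = np.array([(1.0 - alpha) ** order])
    return b, a


class PeripheryKernel:
    """Streaming implementation of the periphery.

    ``process_block`` consumes an arbitrary-length chunk of the audio-rate
    pressure waveform together with a (scalar or per-sample) linear tip-gain
    factor and returns the decimated envelope and fiber rates for that chunk.
    Filter and adaptation states persist across calls, so feeding a waveform
    in blocks is numerically identical to feeding it at once.
    """

    def __init__(self, config: PeripheryConfig, sample_rate: float):
        self.config = config
        self.fs = float(sample_rate)
        if self.fs < 10.0 * config.cf:
            raise ValueError("audio sample rate must be at least 10x the channel CF")
        erb = config.cf / config.q_erb
        self._bt, self._at = _complex_resonator_coeffs(config.cf, 1.019 * erb, 4, self.fs)
        self._btl, self._atl = _complex_resonator_coeffs(
            config.cf, config.tail_bandwidth, 2, self.fs
        )
        self._tail_gain = 10.0 ** (-config.tail_attenuation_db / 20.0)
        self._blp, self._alp = _onepole_lowpass_coeffs(config.ihc_cutoff, 4, self.fs)
        # envelope value produced by a 0 dB SPL CF tone at full gain:
        # half-wave rectified sinusoid of amplitude A has mean A / pi
        self._env_ref = np.sqrt(2.0) * P_REF / np.pi

        self._zi_tip = np.zeros(4, dtype=complex)
        self._zi_tail = np.zeros(2, dtype=complex)
        self._zi_lp = np.zeros(4)
        # resource starts at its steady state for silence (spont-only drive)
        self._q = {"hsr": self._q_silence(config.hsr),
                   "lsr": self._q_silence(config.lsr)}
        self._decim = int(round(self.fs / config.rate_fs))
        if abs(self.fs / self._decim - config.rate_fs) > 1e-6:
            raise ValueError("audio rate must be an integer multiple of rate_fs")
        self._decim_phase = 0

    @staticmethod
    def _q_silence(fiber: FiberParams) -> float:
        if not np.isfinite(fiber.depletion_capacity):
            return 1.0
        return fiber.q_steady(fiber.spont)

    # -- stages -------------------------------------------------------------

    def _filter_block(self, x: np.ndarray, gain_lin: Union[float, np.ndarray]) -> np.ndarray:
        tip_in = x * gain_lin
        tip, self._zi_tip = lfilter(self._bt, self._at, tip_in.astype(complex),
                                    zi=self._zi_tip)
        tail, self._zi_tail = lfilter(self._btl, self._atl, x.astype(complex),
                                      zi=self._zi_tail)
        return 2.0 * np.real(tip) + self._tail_gain * 2.0 * np.real(tail)

    def _ihc_block(self, bm: np.ndarray) -> np.ndarray:
        rect = np.maximum(bm, 0.0)
        compressed = rect / (1.0 + rect / self.config.ihc_sat)
        env, self._zi_lp = lfilter(self._blp, self._alp, compressed, zi=self._zi_lp)
        return env

    def _decimate_block(self, env: np.ndarray) -> np.ndarray:
        start = (-self._decim_phase) % self._decim
        out = env[start::self._decim]
        self._decim_phase = (self._decim_phase + len(env)) % self._decim
        return out

    def _synapse_block(self, env10k: np.ndarray, fiber: FiberParams, key: str) -> np.ndarray:
        level = 20.0 * np.log10(np.maximum(env10k, 1e-30) / self._env_ref)
        static = fiber.spont + (fiber.sat - fiber.spont) * expit(
            (level - fiber.midpoint) / fiber.slope)
        if fiber.sloping_rate > 0.0:
            static = static + fiber.sloping_rate * np.maximum(
                level - fiber.sloping_knee, 0.0)
        if not np.isfinite(fiber.depletion_capacity):
            return static
        dt = 1.0 / self.config.rate_fs
        q = self._q[key]
        out = np.empty_like(static)
        inv_tau = dt / fiber.adapt_tau
        inv_cap = dt / fiber.depletion_capacity
        for i in range(len(static)):
            out[i] = q * static[i]
            q += (1.0 - q) * inv_tau - out[i] * inv_cap
            q = min(max(q, 0.0), 1.0)
        self._q[key] = q
        return out

    # -- public -------------------------------------------------------------

    def process_block(self, x: np.ndarray, gain_db: Union[float, np.ndarray] = 0.0):
        """Run one chunk through the full chain.

        Returns (env, hsr_rate, lsr_rate), all at ``config.rate_fs``.
        ``gain_db`` is the MOC gain trajectory value(s), in [-gain_range, 0].
        """
        gmin = np.min(gain_db) if np.ndim(gain_db) else gain_db
        gmax = np.max(gain_db) if np.ndim(gain_db) else gain_db
        if gmin < -self.config.gain_range - 1e-9 or gmax > 1e-9:
            raise ValueError(
                f"gain must lie in [{-self.config.gain_range}, 0] dB, got "
                f"[{gmin:.2f}, {gmax:.2f}]"
            )
        gain_lin = 10.0 ** (np.asarray(gain_db, dtype=float) / 20.0)
        bm = self._filter_block(x, gain_lin)
        env = self._ihc_block(bm)
        env10 = self._decimate_block(env)
        hsr = self._synapse_block(env10, self.config.hsr, "hsr")
        lsr = self._synapse_block(env10, self.config.lsr, "lsr")
        return env10, hsr, lsr


# -- offline convenience wrappers (single pass, full gain unless given) ------


def _gain_at_audio_rate(gain, n: int, fs: float) -> Union[float, np.ndarray]:
    """Resample a GainTrajectory-like object (gain, sample_rate) onto n audio samples."""
    if gain is None:
        return 0.0
    if np.ndim(gain) == 0:
        return float(gain)
    g = np.asarray(gain.gain if hasattr(gain, "gain") else gain, dtype=float)
    src_fs = getattr(gain, "sample_rate", fs)
    t = np.arange(n) / fs
    return np.interp(t, np.arange(len(g)) / src_fs, g)


def cochlear_filter(stimulus: Stimulus, gain, config: PeripheryConfig) -> np.ndarray:
    """Band-limited cochlear output at CF (audio rate) for a given gain trajectory."""
    kernel = PeripheryKernel(config, stimulus.sample_rate)
    g = _gain_at_audio_rate(gain, len(stimulus.samples), stimulus.sample_rate)
    gmin = np.min(g) if np.ndim(g) else g
    gmax = np.max(g) if np.ndim(g) else g
    if gmin < -config.gain_range - 1e-9 or gmax > 1e-9:
        raise ValueError("gain outside [-gain_range, 0] dB")
    gain_lin = 10.0 ** (np.asarray(g, dtype=float) / 20.0)
    return kernel._filter_block(stimulus.samples, gain_lin)


def ihc_transduce(bm_signal: np.ndarray, config: PeripheryConfig,
                  sample_rate: float) -> np.ndarray:
    """IHC transduction: rectify, saturate, low-pass.  Output at the audio rate."""
    kernel = PeripheryKernel(config, sample_rate)
    return kernel._ihc_block(np.asarray(bm_signal, dtype=float))


def synapse_rate(ihc_signal: np.ndarray, fiber: FiberParams,
                 config: PeripheryConfig, landmarks: Optional[dict] = None,
                 stage: str = "HSR") -> RateResponse:
    """Adapting synapse: IHC envelope (at rate_fs) -> instantaneous rate."""
    kernel = PeripheryKernel(config, config.rate_fs * 10)  # fs unused by synapse
    key = "hsr" if stage.upper() == "HSR" else "lsr"
    rate = kernel._synapse_block(np.asarray(ihc_signal, dtype=float), fiber, key)
    return RateResponse(stage=stage, rate=rate, sample_rate=config.rate_fs,
                        landmarks=dict(landmarks or {}))


def an_response(stimulus: Stimulus, gain, config: PeripheryConfig,
                fiber: str = "hsr") -> RateResponse:
    """Full open-loop AN response (gain=None means the no-efferent model, 0 dB)."""
    kernel = PeripheryKernel(config, stimulus.sample_rate)
    g = _gain_at_audio_rate(gain, len(stimulus.samples), stimulus.sample_rate)
    _, hsr, lsr = kernel.process_block(stimulus.samples, g)
    if fiber.lower() == "hsr":
        return RateResponse("HSR", hsr, config.rate_fs, dict(stimulus.landmarks))
    return RateResponse("WDR", lsr, config.rate_fs, dict(stimulus.landmarks))
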