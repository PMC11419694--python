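"""Tone masker / probe stimulus synthesis.

All stimuli in the forward-masking experiments are pure tones: a masker
followed, after a silent gap, by a brief probe.  Levels are specified in
dB SPL (re 20 uPa RMS of the steady portion), ramps are raised-cosine,
and the roving-level paradigm draws the masker level per interval from a
truncated Gaussian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.io import wavfile

__all__ = [
    "P_REF",
    "ToneSpec",
    "TrialSpec",
    "RoveSpec",
    "Stimulus",
    "make_tone",
    "am_tone",
    "assemble_trial",
    "draw_rove_level",
    "export_wav",
]

#: Reference pressure for dB SPL, Pa.
P_REF = 20e-6


def spl_to_amplitude(level_db_spl: float) -> float:
    """Peak amplitude (Pa) of a pure tone whose RMS corresponds to ``level_db_spl``."""
    return np.sqrt(2.0) * P_REF * 10.0 ** (level_db_spl / 20.0)


@dataclass(frozen=True)
class ToneSpec:
    """A pure tone: frequency (Hz), duration (s), level (dB SPL), raised-cosine ramps (s)."""

    frequency: float
    duration: float
    level: float
    ramp_duration: float = 0.002

    def __post_init__(self) -> None:
        if not self.frequency > 0:
            raise ValueError(f"frequency must be positive, got {self.frequency}")
        if not self.duration > 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if self.ramp_duration < 0 or 2.0 * self.ramp_duration > self.duration + 1e-12:
            raise ValueError(
                f"ramps ({self.ramp_duration} s) must fit twice into duration ({self.duration} s)"
            )
        if not np.isfinite(self.level):
            raise ValueError("level must be finite")


@dataclass(frozen=True)
class TrialSpec:
    """One 2IFC interval: pre-silence | masker | gap | probe (or silence) | post-silence.

    ``delay`` is measured from masker offset to probe onset.  When
    ``probe_present`` is False the probe segment is silence of equal duration,
    so target and standard intervals have identical timelines.  ``masker`` may
    be None for probe-in-quiet trials.
    """

    probe: ToneSpec
    masker: Optional[ToneSpec] = None
    delay: float = 0.0
    probe_present: bool = True
    pre_silence: float = 0.05
    post_silence: float = 0.2

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise ValueError("masker-probe delay must be non-negative")
        if self.pre_silence < 0 or self.post_silence < 0:
            raise ValueError("silent padding must be non-negative")

    @property
    def masker_onset(self) -> Optional[float]:
        return self.pre_silence if self.masker is not None else None

    @property
    def masker_offset(self) -> Optional[float]:
        if self.masker is None:
            return None
        return self.pre_silence + self.masker.duration

    @property
    def probe_onset(self) -> float:
        if self.masker is None:
            return self.pre_silence + self.delay
        return self.pre_silence + self.masker.duration + self.delay

    @property
    def probe_offset(self) -> float:
        return self.probe_onset + self.probe.duration

    @property
    def total_duration(self) -> float:
        return self.probe_offset + self.post_silence

    def with_probe_level(self, level: float) -> "TrialSpec":
        return replace(self, probe=replace(self.probe, level=level))

    def with_masker_level(self, level: float) -> "TrialSpec":
        if self.masker is None:
            raise ValueError("trial has no masker")
        return replace(self, masker=replace(self.masker, level=level))


@dataclass(frozen=True)
class RoveSpec:
    """Truncated-Gaussian roving masker level: mean (dB SPL), sd (dB), cut at ±k·sd."""

    mean_level: float = 70.0
    sd: float = 6.0
    k: float = 3.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if not self.k > 0:
            raise ValueError("truncation factor k must be positive")


@dataclass
class Stimulus:
    """Sampled sound-pressure waveform (Pa) with trial landmarks (s)."""

    samples: np.ndarray
    sample_rate: float
    spec: TrialSpec
    landmarks: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.sample_rate


def _raised_cosine_envelope(n: int, n_ramp: int) -> np.ndarray:
    env = np.ones(n)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] *= ramp
        env[-n_ramp:] *= ramp[::-1]
    return env


def make_tone(spec: ToneSpec, sample_rate: float) -> np.ndarray:
    """Synthesize a ramped tone segment; steady-portion RMS realizes ``spec.level``."""
    if sample_rate < 10.0 * spec.frequency:
        raise ValueError(
            f"sample rate {sample_rate} Hz too low for a {spec.frequency} Hz tone "
            "(need at least 10 samples per cycle)"
        )
    n = int(round(spec.duration * sample_rate))
    n_ramp = int(round(spec.ramp_duration * sample_rate))
    t = np.arange(n) / sample_rate
    tone = spl_to_amplitude(spec.level) * np.sin(2.0 * np.pi * spec.frequency * t)
    return tone * _raised_cosine_envelope(n, n_ramp)


def am_tone(
    carrier_freq: float,
    mod_freq: float,
    depth: float,
    duration: float,
    level: float,
    sample_rate: float,
    ramp_duration: float = 0.01,
) -> np.ndarray:
    """Sinusoidally amplitude-modulated tone; ``level`` refers to the carrier."""
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    carrier = spl_to_amplitude(level) * np.sin(2.0 * np.pi * carrier_freq * t)
    mod = 1.0 + depth * np.sin(2.0 * np.pi * mod_freq * t - np.pi / 2.0)
    n_ramp = int(round(ramp_duration * sample_rate))
    return carrier * mod * _raised_cosine_envelope(n, n_ramp)


def assemble_trial(spec: TrialSpec, sample_rate: float) -> Stimulus:
    """Concatenate pre-silence | masker | delay gap | probe-or-silence | post-silence."""
    n_pre = int(round(spec.pre_silence * sample_rate))
    n_delay = int(round(spec.delay * sample_rate))
    n_post = int(round(spec.post_silence * sample_rate))

    parts = [np.zeros(n_pre)]
    if spec.masker is not None:
        parts.append(make_tone(spec.masker, sample_rate))
    parts.append(np.zeros(n_delay))
    probe_seg = make_tone(spec.probe, sample_rate)
    if not spec.probe_present:
        probe_seg = np.zeros_like(probe_seg)
    parts.append(probe_seg)
    parts.append(np.zeros(n_post))
    samples = np.concatenate(parts)

    landmarks = {
        "masker_onset": spec.masker_onset,
        "masker_offset": spec.masker_offset,
        "probe_onset": spec.probe_onset,
        "probe_offset": spec.probe_offset,
    }
    return Stimulus(samples=samples, sample_rate=sample_rate, spec=spec, landmarks=landmarks)


def draw_rove_level(rove: RoveSpec, rng: np.random.Generator) -> float:
    """Draw one masker level from the truncated Gaussian (rejection sampling).

    Redraw-until-inside rather than clipping, so no probability mass piles up
    at the +/- k·sd edges.
    """
    if rove.sd == 0:
        return rove.mean_level
    lo = rove.mean_level - rove.k * rove.sd
    hi = rove.mean_level + rove.k * rove.sd
    while True:
        x = rng.normal(rove.mean_level, rove.sd)
        if lo <= x <= hi:
            return float(x)


def export_wav(stimulus: Stimulus, path: str | Path) -> Path:
    """Write a float32 WAV (peak-normalized) plus a JSON sidecar for calibration.

    The sidecar records the peak scale factor, sample rate, and landmarks so
    the absolute pressure waveform is recoverable from the normalized file.
    """
    path = Path(path)
    if len(stimulus.samples) == 0:
        raise ValueError("refusing to write a zero-length stimulus")
    peak = float(np.max(np.abs(stimulus.samples)))
    scale = peak if peak > 0 else 1.0
    data = (stimulus.samples / scale).astype(np.float32)
    wavfile.write(path, int(stimulus.sample_rate), data)
    sidecar = {
        "peak_pa": scale,
        "sample_rate": stimulus.sample_rate,
        "landmarks": stimulus.landmarks,
        "probe_level_db_spl": stimulus.spec.probe.level,
        "masker_level_db_spl": (
            stimulus.spec.masker.level if stimulus.spec.masker is not None else None
        ),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))
    return path
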