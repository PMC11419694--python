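"""YAML configuration for model and experiment parameters.

A config file mirrors the stimulus-parameter table of the paradigms plus the
model sections (``periphery``, ``moc``, ``sfie``, ``modfilter``, ``decision``).
Every key is optional; omitted keys fall back to the calibrated defaults.
"""

from __future__ import annotations

from dataclasses import asdict, fields, replace
from pathlib import Path
from typing import Any, Optional

import yaml

from .efferent_loop import MocConfig
from .midbrain import ModFilterConfig, SfieConfig
from .periphery import FiberParams, PeripheryConfig
from .psychoacoustics import DecisionConfig

__all__ = ["ModelBundle", "load_config", "dump_config", "default_bundle"]


class ModelBundle:
    """The four model config sections plus the decision-stage config."""

    def __init__(self,
                 periphery: Optional[PeripheryConfig] = None,
                 moc: Optional[MocConfig] = None,
                 sfie: Optional[SfieConfig] = None,
                 modfilter: Optional[ModFilterConfig] = None,
                 decision: Optional[DecisionConfig] = None,
                 experiment: Optional[dict] = None):
        self.periphery = periphery or PeripheryConfig()
        self.moc = moc or MocConfig()
        self.sfie = sfie or SfieConfig()
        self.modfilter = modfilter or ModFilterConfig()
        self.decision = decision or DecisionConfig()
        self.experiment = dict(experiment or {})

    def to_dict(self) -> dict:
        return {
            "periphery": asdict(self.periphery),
            "moc": asdict(self.moc),
            "sfie": asdict(self.sfie),
            "modfilter": asdict(self.modfilter),
            "decision": asdict(self.decision),
            "experiment": self.experiment,
        }


def _build(cls, defaults, section: dict[str, Any]):
    known = {f.name for f in fields(cls)}
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return replace(defaults, **section)


def load_config(path: str | Path) -> ModelBundle:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    periphery_raw = dict(raw.get("periphery", {}))
    for fiber_key in ("hsr", "lsr"):
        if fiber_key in periphery_raw:
            base = getattr(PeripheryConfig(), fiber_key)
            periphery_raw[fiber_key] = _build(FiberParams, base,
                                              periphery_raw[fiber_key])
    return ModelBundle(
        periphery=_build(PeripheryConfig, PeripheryConfig(), periphery_raw),
        moc=_build(MocConfig, MocConfig(), raw.get("moc", {})),
        sfie=_build(SfieConfig, SfieConfig(), raw.get("sfie", {})),
        modfilter=_build(ModFilterConfig, ModFilterConfig(),
                         raw.get("modfilter", {})),
        decision=_build(DecisionConfig, DecisionConfig(),
                        raw.get("decision", {})),
        experiment=raw.get("experiment", {}),
    )


def dump_config(bundle: ModelBundle, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(bundle.to_dict(), sort_keys=False))
    return path


def default_bundle() -> ModelBundle:
    return ModelBundle()
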