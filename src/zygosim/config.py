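"""YAML experiment configuration.

One file configures everything: scene generation, optics, vision, rig
tolerances and injection model, sequencer limits, and outcome arms.
Unknown keys and out-of-range values raise ConfigurationError naming the
offending field.
"""
from __future__ import annotations

import dataclasses

import yaml

from .errors import ConfigurationError
from .optics import OpticsConfig
from .outcomes import ArmConfig
from .rig import InjectionModel, InjectionParams, MechanicalTolerances
from .scene import GeneratorConfig
from .sequencer import SequencerConfig, SimulationConfig
from .vision import RegionConfig, VisionConfig

__all__ = ["load_experiment", "simulation_config_from_dict"]

_SECTIONS = {
    "scene": GeneratorConfig,
    "optics": OpticsConfig,
    "vision": VisionConfig,
    "tolerances": MechanicalTolerances,
    "injection_model": InjectionModel,
    "injection_params": InjectionParams,
    "sequence": SequencerConfig,
}


def _build(cls, section: str, data: dict):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"section '{section}' must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in section '{section}'; "
            f"valid keys: {sorted(names)}")
    fixed = dict(data)
    # YAML lists -> tuples where the dataclass expects pairs
    for k, v in fixed.items():
        if isinstance(v, list) and len(v) == 2 and all(
                isinstance(x, (int, float)) for x in v):
            fixed[k] = tuple(v)
    try:
        return cls(**fixed)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"section '{section}': {exc}") from exc


def simulation_config_from_dict(raw: dict) -> tuple[SimulationConfig,
                                                    GeneratorConfig,
                                                    list[ArmConfig]]:
    raw = raw or {}
    known = set(_SECTIONS) | {"arms", "region"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(
            f"unknown top-level section(s) {sorted(unknown)}; "
            f"valid sections: {sorted(known)}")
    parts = {name: _build(cls, name, raw.get(name))
             for name, cls in _SECTIONS.items()}
    vision = parts["vision"]
    if "region" in raw:
        vision.region = _build(RegionConfig, "region", raw["region"])
    sim = SimulationConfig(
        optics=parts["optics"], vision=vision,
        tolerances=parts["tolerances"],
        injection_model=parts["injection_model"],
        injection_params=parts["injection_params"],
        sequencer=parts["sequence"],
    )
    sim.validate()
    arms = [_build(ArmConfig, f"arms[{i}]", a)
            for i, a in enumerate(raw.get("arms", []) or [])]
    return sim, parts["scene"], arms


def load_experiment(path: str):
    """Load and validate an experiment YAML file.

    Returns (SimulationConfig, GeneratorConfig, list[ArmConfig]).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return simulation_config_from_dict(raw)
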