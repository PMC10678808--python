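"""YAML configuration loading with unit-aware values.

A config file selects a reference scenario and/or overrides individual
parameters.  Lengths may be given as strings with units ("200 um",
"0.34 mm"); plain numbers are taken as SI.  Unknown keys are rejected.

Example
-------
::

    scenario: d
    grid_preset: desk
    spheroid_radius: 340 um
    dt: 1.0
    t_end: 100.0
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .scenarios import GRID_PRESETS, ScenarioConfig, reference_scenarios

__all__ = ["load_config", "parse_quantity"]

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3, "min": 60.0}
_PRESSURE_UNITS = {"Pa": 1.0, "kPa": 1e3}
_VELOCITY_UNITS = {"m/s": 1.0, "mm/s": 1e-3, "um/s": 1e-6}

_QUANTITY_KINDS = {
    "spheroid_radius": _LENGTH_UNITS,
    "spacing": _LENGTH_UNITS,
    "dt": _TIME_UNITS,
    "t_end": _TIME_UNITS,
    "delta_p": _PRESSURE_UNITS,
    "target_velocity": _VELOCITY_UNITS,
}

_ALLOWED_KEYS = {
    "scenario",
    "name",
    "spheroid_radius",
    "spheroid_position",
    "grid_preset",
    "spacing",
    "target_velocity",
    "delta_p",
    "omega_max",
    "dt",
    "t_end",
}


def parse_quantity(value, units: dict) -> float:
    """Parse "200 um" / "1 mm" / bare numbers into SI floats."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = str(value).split()
    if len(parts) != 2:
        raise ValueError(f"malformed quantity {value!r}; expected '<number> <unit>'")
    num, unit = parts
    if unit not in units:
        raise ValueError(f"unknown unit {unit!r} in {value!r}; known: {sorted(units)}")
    return float(num) * units[unit]


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario configuration from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    scenario = raw.pop("scenario", None)
    if scenario is not None:
        refs = reference_scenarios()
        if scenario not in refs:
            raise ValueError(f"unknown scenario {scenario!r}; choose from {sorted(refs)}")
        base = refs[scenario]
    else:
        if "spheroid_radius" not in raw or "spheroid_position" not in raw:
            raise ValueError(
                "config needs either 'scenario' or explicit spheroid_radius/position"
            )
        base = ScenarioConfig(
            name=raw.get("name", "custom"),
            spheroid_radius=parse_quantity(raw["spheroid_radius"], _LENGTH_UNITS),
            spheroid_position=raw["spheroid_position"],
        )
        raw.pop("spheroid_radius")
        raw.pop("spheroid_position")
        raw.pop("name", None)

    overrides = {}
    for key, value in raw.items():
        if key in _QUANTITY_KINDS:
            overrides[key] = parse_quantity(value, _QUANTITY_KINDS[key])
        else:
            overrides[key] = value
    if "grid_preset" in overrides and overrides["grid_preset"] not in GRID_PRESETS:
        raise ValueError(f"unknown grid preset {overrides['grid_preset']!r}")
    cfg = replace(base, **overrides)
    if cfg.dt <= 0:
        raise ValueError("dt must be positive")
    return cfg
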