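"""Configuration-file loading (TOML or YAML) with strict key validation.

Top-level keys name :class:`TrainingConfig` fields (plus ``animal_id`` and
``experimenter``); optional ``[detector]``, ``[subject]`` and ``[scene]``
tables configure the other components. Unknown keys are rejected by name so a
typo never silently falls back to a default.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Optional

import yaml

from .controller import TrainingConfig
from .errors import ConfigError
from .motion import DetectorConfig
from .simulate import SceneParams, SubjectParams

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All sections of a configuration file."""

    training: TrainingConfig
    detector: Optional[DetectorConfig] = None
    subject: Optional[SubjectParams] = None
    scene: Optional[SceneParams] = None


_SECTIONS = {
    "detector": DetectorConfig,
    "subject": SubjectParams,
    "scene": SceneParams,
}

_NUMERIC = (int, float)


def _coerce(cls: type, data: dict[str, Any], section: str) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown key {key!r} in {section} config")
        hint = fields[key].type
        if isinstance(value, list):
            value = tuple(value)
        if "float" in str(hint) and isinstance(value, bool):
            raise ConfigError(f"{section} key {key!r}: expected a number")
        if "float" in str(hint) and not isinstance(value, _NUMERIC):
            raise ConfigError(
                f"{section} key {key!r}: expected a number, got {value!r}"
            )
        if str(hint) == "int" and not isinstance(value, int):
            raise ConfigError(
                f"{section} key {key!r}: expected an integer, got {value!r}"
            )
        if "str" in str(hint) and "int" not in str(hint) and not isinstance(
            value, str
        ):
            raise ConfigError(
                f"{section} key {key!r}: expected a string, got {value!r}"
            )
        kwargs[key] = value
    try:
        obj = cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"invalid {section} config: {exc}") from None
    if hasattr(obj, "validate"):
        obj.validate()
    return obj


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML (default) or YAML configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(path.read_text()) or {}
    else:
        with path.open("rb") as fh:
            data = tomllib.load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a table/mapping: {path}")
    sections: dict[str, Any] = {}
    top: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTIONS:
            if not isinstance(value, dict):
                raise ConfigError(f"section {key!r} must be a table")
            sections[key] = _coerce(_SECTIONS[key], value, key)
        elif key == "training" and isinstance(value, dict):
            top.update(value)
        else:
            top[key] = value
    training = _coerce(TrainingConfig, top, "training")
    training.validate()
    return RunConfig(training=training, **sections)
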