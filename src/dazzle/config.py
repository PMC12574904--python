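"""Layered run configuration: built-in defaults < YAML file < explicit flags."""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .training import TrainConfig

__all__ = ["resolve_config", "ConfigError"]


class ConfigError(ValueError):
    """Unknown or invalid configuration keys/values."""


def resolve_config(yaml_path: str | Path | None = None,
                   overrides: dict | None = None) -> TrainConfig:
    """Build a :class:`TrainConfig` with precedence flags > YAML > defaults.

    ``overrides`` entries with value ``None`` are treated as "not given".
    Unknown keys raise :class:`ConfigError` listing the valid ones.
    """
    valid = {f.name for f in fields(TrainConfig)}
    merged = asdict(TrainConfig())
    if yaml_path is not None:
        loaded = yaml.safe_load(Path(yaml_path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{yaml_path}: expected a mapping at top level")
        unknown = set(loaded) - valid
        if unknown:
            raise ConfigError(f"unknown config keys {sorted(unknown)}; "
                              f"valid keys: {sorted(valid)}")
        merged.update(loaded)
    for key, val in (overrides or {}).items():
        if val is None:
            continue
        if key not in valid:
            raise ConfigError(f"unknown config key {key!r}; "
                              f"valid keys: {sorted(valid)}")
        merged[key] = val
    try:
        return TrainConfig(**merged)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
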