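"""Configuration loading: YAML files plus flag overrides.

Files are flat key/value mappings mirroring the config dataclass field
names.  Unknown keys are rejected outright; range validation lives in the
dataclasses themselves and reports the offending key.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from ..experiments import TimeSeriesConfig
from ..model_core import ConfigurationError, UnitConfig

__all__ = ["load_unit_config", "load_timeseries_config", "read_config_mapping"]


def read_config_mapping(path: Union[str, Path]) -> dict:
    """Parse a YAML config file into a flat dict (empty file -> {})."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(
            f"{path}: config must be a mapping, got {type(data).__name__}"
        )
    return data


def _build(cls, path, overrides):
    values: dict = {}
    if path is not None:
        values.update(read_config_mapping(path))
    if overrides:
        values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(cls)}
    unknown = sorted(set(values) - known)
    if unknown:
        raise ConfigurationError(
            f"unknown configuration key(s): {', '.join(unknown)}"
        )
    return cls(**values)


def load_unit_config(
    path: Optional[Union[str, Path]] = None,
    overrides: Optional[Mapping] = None,
) -> UnitConfig:
    """Unit configuration from an optional file plus overriding flags."""
    return _build(UnitConfig, path, overrides)


def load_timeseries_config(
    path: Optional[Union[str, Path]] = None,
    overrides: Optional[Mapping] = None,
) -> TimeSeriesConfig:
    """Time-series configuration from an optional file plus overrides."""
    return _build(TimeSeriesConfig, path, overrides)
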