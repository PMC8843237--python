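"""Flat YAML parameter files.

Keys are named exactly as :class:`~acdc.params.ModelParams` fields; unknown
keys are rejected, and values are validated by the dataclass. An empty file
yields the published defaults. ``acdc/data/default_params.yaml`` ships the
full default set for reference and round-trips through ``load_config``.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

from .params import ModelParams

__all__ = ["load_config", "save_config", "default_config_path"]

_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def load_config(path: Union[str, Path]) -> ModelParams:
    """Read a parameter file; defaults fill in everything not overridden."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a flat key: value mapping")
    unknown = sorted(set(data) - _FIELDS)
    if unknown:
        raise ValueError(f"{path}: unknown parameter key(s): {', '.join(unknown)}")
    if "j_na_per_action" in data and data["j_na_per_action"] is not None:
        data["j_na_per_action"] = tuple(data["j_na_per_action"])
    try:
        return ModelParams(**data)
    except (TypeError, ValueError) as err:
        raise ValueError(f"{path}: invalid parameter value ({err})") from err


def save_config(params: ModelParams, path: Union[str, Path]) -> None:
    """Write every parameter as a flat YAML mapping (lossless round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def default_config_path() -> Path:
    """Path of the packaged default parameter file."""
    return Path(resources.files("acdc") / "data" / "default_params.yaml")
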