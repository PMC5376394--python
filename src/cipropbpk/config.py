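"""Loading of the packaged default configuration tables.

Every physiological or drug-specific constant the models need is read from a
human-editable YAML file rather than hard-coded; the functions here return the
parsed dictionaries for the files shipped under :mod:`cipropbpk.data`. Pass a
path to any loader to substitute your own table.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "load_yaml",
    "packaged_config",
    "default_physiology_config",
    "default_ep_config",
    "default_parameters_config",
    "default_strains_config",
]


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Parse a YAML config file into a dictionary."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path!s} does not contain a mapping")
    return data


def packaged_config(name: str) -> dict[str, Any]:
    """Load one of the YAML files shipped with the package."""
    text = resources.files("cipropbpk.data").joinpath(name).read_text(encoding="utf-8")
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"packaged config {name!r} is malformed")
    return data


def default_physiology_config() -> dict[str, Any]:
    return packaged_config("physiology.yaml")


def default_ep_config() -> dict[str, Any]:
    return packaged_config("extracellular_albumin.yaml")


def default_parameters_config() -> dict[str, Any]:
    return packaged_config("parameters.yaml")


def default_strains_config() -> dict[str, Any]:
    return packaged_config("strains.yaml")
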