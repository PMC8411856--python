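"""Package configuration.

All tunable defaults live in one packaged YAML file (``data/defaults.yaml``)
with nested sections per model stage and per crop.  :func:`load_config`
returns those defaults, optionally deep-merged with a user YAML of the same
shape, so a single file can retune any constant without touching code.
"""

from __future__ import annotations

import copy
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["load_config", "defaults", "deep_merge", "GAS_CONSTANT", "T_REF"]

GAS_CONSTANT = 8.314  # J mol-1 K-1
T_REF = 298.15  # K, 25 degrees C reference for all 25C-basis parameters


def _read_packaged_defaults() -> dict:
    text = resources.files("sunshade").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


_DEFAULTS: dict | None = None


def defaults() -> dict:
    """Return a deep copy of the packaged default configuration."""
    global _DEFAULTS
    if _DEFAULTS is None:
        _DEFAULTS = _read_packaged_defaults()
    return copy.deepcopy(_DEFAULTS)


def deep_merge(base: dict, override: Mapping[str, Any]) -> dict:
    """Recursively merge ``override`` into ``base`` (returns ``base``)."""
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(base.get(key), dict):
            deep_merge(base[key], value)
        else:
            base[key] = value
    return base


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict:
    """Load the configuration: packaged defaults, then ``path``, then ``overrides``."""
    cfg = defaults()
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        deep_merge(cfg, user)
    if overrides:
        deep_merge(cfg, overrides)
    return cfg
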