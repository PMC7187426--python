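"""Configuration loading and hashing.

The package ships a single default configuration (``data/defaults.yaml``)
holding every calibrated anchor of the Cameroon analysis.  User overrides are
deep-merged on top of the defaults, so a run is fully described by (config,
seed) and the manifest records a hash of the merged document.
"""

from __future__ import annotations

import copy
import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["load_config", "default_config", "config_hash", "deep_merge"]


def default_config() -> dict:
    """Return a fresh copy of the packaged default configuration."""
    text = resources.files("vitaplan.data").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict:
    """Recursively merge ``override`` into ``base`` (returns a new dict)."""
    out = copy.deepcopy(dict(base))
    for key, val in override.items():
        if key in out and isinstance(out[key], Mapping) and isinstance(val, Mapping):
            out[key] = deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Load the default configuration, optionally merged with a YAML override file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ValueError(f"config override {path!r} must be a mapping")
        cfg = deep_merge(cfg, override)
    return cfg


def config_hash(cfg: Mapping[str, Any]) -> str:
    """Stable short hash of a configuration mapping."""
    canonical = json.dumps(cfg, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
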