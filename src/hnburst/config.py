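"""YAML parameter files for both models.

A config file is a flat mapping of parameter-field names to values, e.g.::

    g_nap: 6.0
    ipump_max: 0.3
    i_app: -0.1

Unknown keys raise immediately, so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .full_model import FullModelParams
from .reduced_model import ReducedModelParams

__all__ = ["load_params", "dump_params"]

_KINDS = {"full": FullModelParams, "2d": ReducedModelParams}


def load_params(path, kind: str = "full", **overrides):
    """Build a parameter set from a YAML file plus keyword overrides."""
    cls = _KINDS.get(kind)
    if cls is None:
        raise ValueError(f"unknown model kind {kind!r}")
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameters {sorted(unknown)}")
    raw.update(overrides)
    return cls(**raw)


def dump_params(params, path) -> None:
    """Write a parameter set as YAML."""
    Path(path).write_text(yaml.safe_dump(asdict(params), sort_keys=False))
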