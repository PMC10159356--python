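"""Key=value configuration files and run manifests.

Simulation configs are plain text, one ``key = value`` per line with ``#``
comments, keys matching :class:`cheatsplit.abm.SimConfig` fields.  Unknown
keys and type errors are rejected with the offending field named.  Every
CLI command writes a JSON manifest beside its outputs recording the
resolved configuration, master seed and output files, so a run can be
reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

from .abm import SimConfig

__all__ = ["load_sim_config", "parse_kv_text", "write_manifest"]

_BOOL = {"true": True, "false": False, "yes": True, "no": False}


def parse_kv_text(text: str) -> dict:
    """Parse ``key = value`` lines (comments and blank lines ignored)."""
    out = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        out[key] = value
    return out


def _coerce(key: str, raw: str, target_type) -> object:
    if raw.lower() in ("none", ""):
        return None
    try:
        if target_type is bool:
            return _BOOL[raw.lower()]
        return target_type(raw)
    except (ValueError, KeyError) as err:
        raise ValueError(f"field {key!r}: cannot parse {raw!r} as {target_type.__name__}") from err


_FIELD_TYPES = {
    "n_genes": int,
    "moi": float,
    "n_cells": int,
    "n_generations": int,
    "mut_rate": float,
    "e": float,
    "y": float,
    "alpha": float,
    "gamma": float,
    "prop_single": float,
    "coinfection": str,
    "beta": float,
    "seed": int,
    "record_every": int,
}


def load_sim_config(path: Optional[str] = None, overrides: Optional[dict] = None) -> SimConfig:
    """Build a :class:`SimConfig` from an optional config file plus override
    values (overrides win).  Unknown keys are rejected; constraint
    violations surface from ``SimConfig`` with the field named."""
    values: dict = {}
    if path is not None:
        values.update(parse_kv_text(Path(path).read_text()))
    for key, val in (overrides or {}).items():
        if val is not None:
            values[key] = val
    kwargs = {}
    for key, raw in values.items():
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key {key!r}")
        kwargs[key] = _coerce(key, str(raw), _FIELD_TYPES[key]) if isinstance(raw, str) else raw
    return SimConfig(**kwargs)


def write_manifest(
    out_dir,
    command: str,
    config: dict,
    seed: Optional[int],
    outputs: list,
) -> Path:
    """Write ``<command>_manifest.json`` beside the outputs."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dataclasses.is_dataclass(config):
        config = dataclasses.asdict(config)
    manifest = {
        "command": command,
        "config": {k: _jsonable(v) for k, v in config.items()},
        "master_seed": seed,
        "artifact_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(Path(p).name) for p in outputs],
    }
    path = out_dir / f"{command}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path


def _jsonable(v):
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    if hasattr(v, "item"):
        return v.item()
    return v
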