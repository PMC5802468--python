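"""Run configuration and artifact serialization.

A run directory always receives the exact resolved configuration, and a
manifest listing every artifact with its SHA-256 checksum.  The config
format is YAML with strict key checking: unknown keys are errors, which
guards against silently misspelled tolerance names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


def load_config(path: str | Path, schema: type) -> object:
    """Load a YAML config into a dataclass, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(schema)}
    unknown = set(raw) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config keys {sorted(unknown)}; valid keys: "
            f"{sorted(fields)}")
    coerced = {}
    for k, v in raw.items():
        if isinstance(v, list):
            v = tuple(v)
        coerced[k] = v
    try:
        return schema(**coerced)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_plain(x) for x in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def dump_config(cfg: object, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(cfg), sort_keys=False))


def sha256_of(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_manifest(outdir: str | Path, extra: dict | None = None) -> Path:
    """List every artifact in a run directory with its checksum."""
    outdir = Path(outdir)
    entries = []
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries.append({
                "path": str(p.relative_to(outdir)),
                "bytes": p.stat().st_size,
                "sha256": sha256_of(p),
            })
    payload = {"artifacts": entries}
    if extra:
        payload.update(extra)
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(payload, indent=1))
    return mpath
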