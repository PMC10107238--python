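"""Configuration files, deterministic CSV tables and run manifests."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Mapping, Sequence

import yaml


class ConfigError(ValueError):
    """Raised for malformed configuration documents; names the offending key."""


def read_config(path: str | Path, allowed_keys: Sequence[str]) -> dict:
    """Read a flat key-value document, rejecting unknown keys by name."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config {path} must be a flat key-value document")
    unknown = sorted(set(raw) - set(allowed_keys))
    if unknown:
        raise ConfigError(f"unknown config key(s): {', '.join(unknown)}")
    return raw


def _format_value(v) -> str:
    if isinstance(v, bool):
        return str(v)
    if isinstance(v, float):
        return format(v, ".12g")
    return str(v)


def write_table(rows: Sequence[Mapping], path: str | Path, columns: Sequence[str]) -> None:
    """Write rows as CSV with a fixed header order; byte-stable per input.

    Every row must carry exactly the declared columns (schema mismatch is an
    error); floats use a 12-significant-digit shortest form.
    """
    path = Path(path)
    lines = [",".join(columns)]
    for i, row in enumerate(rows):
        missing = set(columns) - set(row)
        extra = set(row) - set(columns)
        if missing or extra:
            raise ConfigError(
                f"row {i} does not match schema (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        lines.append(",".join(_format_value(row[c]) for c in columns))
    path.write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class RunManifest:
    """Provenance written alongside every output set."""

    command: str
    config_hash: str
    seed: int | None
    version: str
    timestamp: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def make_manifest(command: str, config: Mapping | None, seed: int | None) -> RunManifest:
    from . import __version__

    blob = json.dumps(config or {}, sort_keys=True, default=str).encode()
    return RunManifest(
        command=command,
        config_hash=hashlib.sha256(blob).hexdigest()[:16],
        seed=seed,
        version=__version__,
        timestamp=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    )
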