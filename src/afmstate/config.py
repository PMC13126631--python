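"""Configuration loading, seeding and provenance.

One global ``--seed`` is expanded into independent per-module substreams
by fixed string labels, so adding a consumer never reshuffles another
module's draws.  Every output directory gets a provenance JSON (config
hash, seed, library versions) sufficient to regenerate it.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from pathlib import Path

import numpy as np
import yaml

__all__ = ["substream", "load_config", "config_hash", "write_provenance"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Independent, reproducible random stream for (seed, label)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


def load_config(path, schema: dict | None = None) -> dict:
    """Load a YAML config; optionally check required keys and types.

    ``schema`` maps key -> type (or tuple of types); missing or
    mistyped keys raise ValueError with the offending key named.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    for key, expected in (schema or {}).items():
        if key not in cfg:
            raise ValueError(f"{path}: missing required key {key!r}")
        if not isinstance(cfg[key], expected):
            raise ValueError(f"{path}: key {key!r} must be {expected}")
    return cfg


def config_hash(obj) -> str:
    """Stable SHA-256 of a JSON-serialisable configuration object."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_provenance(out_dir, *, seed: int, config=None, extra=None) -> Path:
    """Write provenance.json next to the outputs of a pipeline step."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = {
        "seed": int(seed),
        "config_hash": config_hash(config or {}),
        "config": config or {},
        "versions": {"afmstate": __version__, "numpy": np.__version__},
    }
    if extra:
        record.update(extra)
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
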