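"""Serialization helpers and random-state management.

Every artifact (dataset, model) is saved as a directory whose
``meta.json`` is written with canonical key ordering and a fixed float
representation, so that save -> load -> save is byte-identical. Sidecar
tables are plain TSV. Seeds for replicas, folds and derived components
come from :func:`derive_seed`, a fixed hash that is stable across
processes and platforms.
"""

from __future__ import annotations

import hashlib
import json
import random
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1

META_FILENAME = "meta.json"


def canonical_json(obj) -> str:
    """Serialize to JSON with sorted keys and stable float repr."""
    return json.dumps(obj, sort_keys=True, indent=2, ensure_ascii=False,
                      allow_nan=False, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_meta(directory: str | Path, meta: dict) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = dict(meta)
    meta.setdefault("schema_version", SCHEMA_VERSION)
    path = directory / META_FILENAME
    path.write_text(canonical_json(meta) + "\n", encoding="utf-8")
    return path


def load_meta(directory: str | Path) -> dict:
    directory = Path(directory)
    path = directory / META_FILENAME
    if not path.exists():
        raise FileNotFoundError(f"no {META_FILENAME} in {directory}")
    meta = json.loads(path.read_text(encoding="utf-8"))
    version = meta.get("schema_version", 0)
    if version > SCHEMA_VERSION:
        raise ValueError(
            f"artifact schema_version {version} newer than supported {SCHEMA_VERSION}"
        )
    for rel in meta.get("files", []):
        if not (directory / rel).exists():
            raise FileNotFoundError(f"manifest file missing: {rel} (in {directory})")
    return meta


def content_hash(path: str | Path) -> str:
    """SHA-256 of a file's bytes, hex-encoded."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def derive_seed(base: int, label: str) -> int:
    """Stable sub-seed for a labelled component of a seeded computation.

    Pure function of ``(base, label)`` via SHA-256; the result fits in a
    signed 32-bit integer so it is accepted by every downstream RNG.
    """
    digest = hashlib.sha256(f"{int(base)}:{label}".encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def set_random_state(seed: int) -> None:
    """Seed the global ``random`` and legacy numpy RNGs."""
    random.seed(seed)
    np.random.seed(seed % (2**32))
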