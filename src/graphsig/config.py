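"""Versioned configuration files (pharmacophore rules, descriptor manifest,
fragment panel) shipped as package data, with content hashes for provenance."""

from __future__ import annotations

import hashlib
import json
from functools import lru_cache
from importlib import resources
from typing import Any

_DATA_PACKAGE = "graphsig.data"


def _read_text(filename: str) -> str:
    return resources.files(_DATA_PACKAGE).joinpath(filename).read_text(encoding="utf-8")


@lru_cache(maxsize=None)
def load_config(filename: str) -> dict[str, Any]:
    """Load a JSON config shipped with the package.

    The returned dict gains a ``config_hash`` key: the SHA-256 of the raw
    file bytes, so every downstream artifact can record exactly which rule
    table produced it.
    """
    text = _read_text(filename)
    cfg = json.loads(text)
    cfg["config_hash"] = hashlib.sha256(text.encode("utf-8")).hexdigest()
    return cfg


def pharmacophore_config() -> dict[str, Any]:
    return load_config("pharmacophores.json")


def descriptor_config() -> dict[str, Any]:
    return load_config("descriptors.json")


def fragment_config() -> dict[str, Any]:
    return load_config("fragments.json")


def hash_mapping(mapping: dict[str, Any]) -> str:
    """Deterministic SHA-256 of an arbitrary JSON-serialisable mapping."""
    payload = json.dumps(mapping, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()
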