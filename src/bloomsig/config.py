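"""YAML configuration shared by the pipeline subcommands."""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional

import yaml

from .bloom_matrix import packed_rows
from .errors import ConfigurationError
from .kmers import BloomParams, KmerScheme

logger = logging.getLogger(__name__)

_REQUIRED = ("k", "m", "h", "sequence_type", "output_dir")
_KNOWN = set(_REQUIRED) | {
    "canonical", "max_memory", "workers", "input_mode", "input_list",
    "input_file", "seed",
}

_SIZE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*([KMGT]i?B|B)?\s*$", re.IGNORECASE)
_SIZE_UNITS = {
    None: 1, "B": 1,
    "KB": 10**3, "MB": 10**6, "GB": 10**9, "TB": 10**12,
    "KIB": 1 << 10, "MIB": 1 << 20, "GIB": 1 << 30, "TIB": 1 << 40,
}


def parse_size(value) -> int:
    """Accept plain byte counts or human-readable sizes like ``4GiB``."""
    if isinstance(value, int):
        return value
    m = _SIZE_RE.match(str(value))
    if not m:
        raise ConfigurationError(f"cannot parse memory size {value!r}")
    unit = m.group(2).upper() if m.group(2) else None
    return int(float(m.group(1)) * _SIZE_UNITS[unit])


@dataclass
class Config:
    k: int
    m: int
    h: int
    sequence_type: str
    output_dir: Path
    canonical: bool
    max_memory: int
    workers: int
    input_mode: str = "per_file"            # per_file | per_record
    input_list: List[Path] = field(default_factory=list)
    input_file: Optional[Path] = None
    seed: int = 0

    @property
    def bloom_params(self) -> BloomParams:
        scheme = KmerScheme(
            k=self.k, alphabet=self.sequence_type,
            canonical=self.canonical and self.sequence_type == "nucleotide",
        )
        return BloomParams(m=self.m, h=self.h, scheme=scheme, seed=self.seed)


def parse_config(path) -> Config:
    """Load and validate a YAML configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"configuration root must be a mapping, got {type(raw).__name__}")
    unknown = sorted(set(raw) - _KNOWN)
    if unknown:
        logger.warning("ignoring unknown configuration keys: %s", ", ".join(unknown))
    missing = sorted(k for k in _REQUIRED if k not in raw)
    if missing:
        raise ConfigurationError(f"missing required configuration keys: {', '.join(missing)}")
    seq_type = raw["sequence_type"]
    if seq_type not in ("nucleotide", "amino_acid"):
        raise ConfigurationError(
            f"sequence_type must be 'nucleotide' or 'amino_acid', got {seq_type!r}"
        )
    canonical = raw.get("canonical", seq_type == "nucleotide")
    max_memory = parse_size(raw.get("max_memory", 1 << 30))
    m = int(raw["m"])
    if max_memory < packed_rows(m):
        raise ConfigurationError(
            f"max_memory ({max_memory} B) is below one packed Bloom column "
            f"({packed_rows(m)} B); raise max_memory or lower m"
        )
    workers = int(raw.get("workers", os.cpu_count() or 1))
    if workers < 1:
        raise ConfigurationError("workers must be >= 1")
    input_mode = raw.get("input_mode", "per_file")
    if input_mode not in ("per_file", "per_record"):
        raise ConfigurationError("input_mode must be 'per_file' or 'per_record'")
    cfg = Config(
        k=int(raw["k"]),
        m=m,
        h=int(raw["h"]),
        sequence_type=seq_type,
        output_dir=Path(raw["output_dir"]),
        canonical=bool(canonical),
        max_memory=max_memory,
        workers=workers,
        input_mode=input_mode,
        input_list=[Path(p) for p in raw.get("input_list", [])],
        input_file=Path(raw["input_file"]) if raw.get("input_file") else None,
        seed=int(raw.get("seed", 0)),
    )
    cfg.bloom_params  # raises on invariant violations (k, m, h, canonical)
    return cfg
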