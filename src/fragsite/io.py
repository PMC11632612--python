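"""Shared I/O: genomic intervals, BED/bedGraph readers, tabular writers and run configuration.

All coordinates are 0-based, half-open, everywhere in the package. Readers
raise :class:`FormatError` with the offending line number on malformed input.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml


class FormatError(ValueError):
    """Malformed input file; message carries the file path and line number."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Floor of the interval midpoint (used as the 'center' of a repeat locus)."""
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


_BED_SKIP_PREFIXES = ("track", "browser", "#")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read a BED file (≥3 columns) into a list of intervals.

    The 4th column, when present, is stored as the interval name. Track /
    browser / comment header lines are skipped. Raises :class:`FormatError`
    naming the line on malformed records (including start >= end).
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns, got {len(fields)}")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else None
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name=name, strand=strand))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_bedgraph(path: str | Path) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Read a bedGraph file into per-chromosome (starts, ends, values) arrays.

    Intervals are sorted by start per chromosome and checked for overlap;
    overlapping intervals raise :class:`FormatError`. Values are parsed as
    floats (scientific notation accepted). An empty file yields an empty
    dict with a warning.
    """
    path = Path(path)
    chroms: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(_BED_SKIP_PREFIXES):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinates or non-numeric value") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval {start}-{end}")
            chroms.setdefault(fields[0], []).append((start, end, value))
    if not chroms:
        warnings.warn(f"{path}: empty bedGraph", stacklevel=2)
        return {}
    out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, rows in chroms.items():
        rows.sort(key=lambda r: r[0])
        starts = np.array([r[0] for r in rows], dtype=np.int64)
        ends = np.array([r[1] for r in rows], dtype=np.int64)
        values = np.array([r[2] for r in rows], dtype=float)
        if np.any(ends[:-1] > starts[1:]):
            i = int(np.argmax(ends[:-1] > starts[1:]))
            raise FormatError(
                f"{path}: overlapping intervals on {chrom} near {starts[i + 1]}"
            )
        out[chrom] = (starts, ends, values)
    return out


def write_bedgraph(path: str | Path, track: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track):
            starts, ends, values = track[chrom]
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{int(s)}\t{int(e)}\t{v:.10g}\n")


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Thresholds, seeds and presets shared across pipeline stages.

    Defaults mirror the documented analysis choices: spanning FISH signals
    split 50/50 between sides, a reconstructed background breakage rate of
    0.008 per metaphase per band, an MNase retention threshold of 0.1, and
    the ±50 kb / ±500 kb feature windows.
    """

    seed: int = 0
    spanning_split: float = 0.5
    background_rate: float = 0.008
    retention_threshold: float = 0.1
    alpha: float = 0.05
    ci_alpha: float = 0.01
    window_sizes: tuple[int, ...] = (50_000, 500_000)
    digest: str = "EcoRI_BamHI"
    outdir: str = "fragsite_out"

    def __post_init__(self) -> None:
        if not 0.0 <= self.spanning_split <= 1.0:
            raise ValueError("spanning_split must lie in [0, 1]")
        if not 0.0 < self.background_rate < 1.0:
            raise ValueError("background_rate must lie in (0, 1)")
        if not 0.0 < self.retention_threshold < 1.0:
            raise ValueError("retention_threshold must lie in (0, 1)")
        for a in (self.alpha, self.ci_alpha):
            if not 0.0 < a < 1.0:
                raise ValueError("significance levels must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window_sizes"] = list(self.window_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "window_sizes" in d:
            d["window_sizes"] = tuple(d["window_sizes"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def json_report(payload: dict, config: RunConfig | None = None) -> str:
    """Serialize a stage report deterministically (sorted keys, no timestamps)."""
    from . import __version__

    body = dict(payload)
    body["software_version"] = __version__
    if config is not None:
        body["config_hash"] = config.config_hash()
        body["seed"] = config.seed
    return json.dumps(body, sort_keys=True, indent=2, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON-serializable: {type(obj)}")
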