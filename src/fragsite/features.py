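"""Windowed genomic-feature comparison around repeat loci.

Folate-sensitive fragile sites caused by CGG-motif repeats share local
sequence and chromatin-organisation features (GC content, DNA-shape
parameters, replication-origin signal, CTCF/CpG-island boundary density).
This module aggregates arbitrary bedGraph-style tracks in windows centered
on repeat loci, selects length-matched control repeat sets, and compares
the fragile-site and control window distributions with a two-sided
Wilcoxon rank-sum test, with Benjamini–Hochberg-adjusted p-values emitted
alongside raw ones.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import read_bedgraph

logger = logging.getLogger(__name__)

__all__ = [
    "Locus",
    "LocusSet",
    "FeatureTrack",
    "WindowStat",
    "SetComparison",
    "window_aggregate",
    "select_controls",
    "compare_sets",
    "boundary_density",
    "bh_adjust",
]


@dataclass(frozen=True)
class Locus:
    """A repeat locus with its unit count and GC fraction."""

    chrom: str
    start: int
    end: int
    id: str
    repeat_units: float = 1.0
    gc_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid locus {self.id}")
        if self.repeat_units <= 0:
            raise ValueError(f"locus {self.id}: repeat_units must be > 0")

    @property
    def center(self) -> int:
        """Floor of the repeat midpoint; windows are centered here."""
        return (self.start + self.end) // 2


@dataclass
class LocusSet:
    loci: list[Locus]
    label: str = ""

    def __len__(self) -> int:
        return len(self.loci)

    def disjoint_from(self, other: "LocusSet") -> bool:
        for a in self.loci:
            for b in other.loci:
                if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                    return False
        return True


class FeatureTrack:
    """A per-chromosome piecewise-constant signal (bedGraph semantics).

    Stores sorted non-overlapping (starts, ends, values) arrays per
    chromosome. Aggregation is invariant to splitting an interval into
    adjacent sub-intervals with the same value.
    """

    def __init__(self, data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
                 name: str = ""):
        self.name = name
        self.data = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if np.any(ends[:-1] > starts[1:]):
                raise ValueError(f"overlapping track intervals on {chrom}")
            self.data[chrom] = (starts, ends, values)

    @classmethod
    def from_bedgraph(cls, path, name: str = "") -> "FeatureTrack":
        return cls(read_bedgraph(path), name=name)

    def window_mean(self, chrom: str, lo: int, hi: int) -> float:
        """Length-weighted mean of track values overlapping [lo, hi).

        The denominator is the covered length only, so windows clipped at
        track/chromosome ends are averaged over the part that has data.
        Returns NaN when the window has no coverage.
        """
        if chrom not in self.data:
            return math.nan
        starts, ends, values = self.data[chrom]
        ov = np.minimum(ends, hi) - np.maximum(starts, lo)
        ov = np.clip(ov, 0, None)
        covered = ov.sum()
        if covered == 0:
            return math.nan
        return float(np.dot(ov, values) / covered)


@dataclass(frozen=True)
class WindowStat:
    locus_id: str
    half_width: int
    value: float  # mean for tracks, count for point features


@dataclass(frozen=True)
class SetComparison:
    feature: str
    half_width: int
    p_value: float
    direction: int  # sign of (median fsfs - median control)
    n_fsfs: int
    n_control: int
    n_dropped: int = 0


def window_aggregate(
    track: FeatureTrack, loci: LocusSet, half_width: int, mode: str = "mean"
) -> list[WindowStat]:
    """Per-locus track mean (or point-feature count) in ±half_width windows."""
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    out = []
    for locus in loci.loci:
        lo = max(locus.center - half_width, 0)
        hi = locus.center + half_width
        if mode == "mean":
            value = track.window_mean(locus.chrom, lo, hi)
            if math.isnan(value):
                logger.warning("locus %s has no track coverage for %s",
                               locus.id, track.name or "track")
        elif mode == "count":
            value = _count_midpoints(track, locus.chrom, lo, hi)
        else:
            raise ValueError("mode must be 'mean' or 'count'")
        out.append(WindowStat(locus.id, half_width, value))
    return out


def _count_midpoints(track: FeatureTrack, chrom: str, lo: int, hi: int) -> float:
    if chrom not in track.data:
        return 0.0
    starts, ends, _ = track.data[chrom]
    mid = (starts + ends) // 2
    return float(np.count_nonzero((mid >= lo) & (mid < hi)))


def select_controls(
    candidates: LocusSet,
    min_units: float = 4.5,
    n_target: int | None = None,
    seed: int | None = None,
) -> tuple[LocusSet, float]:
    """Filter control repeats by unit count and report their median length.

    Keeps candidates with repeat_units > min_units, optionally subsampling
    to ``n_target`` without replacement; returns the selection and the
    median repeat length of the kept loci.
    """
    kept = [l for l in candidates.loci if l.repeat_units > min_units]
    if not kept:
        raise ValueError(f"no candidates with repeat_units > {min_units}")
    if n_target is not None:
        if len(kept) < n_target:
            raise ValueError(f"only {len(kept)} candidates after filtering, need {n_target}")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(kept), size=n_target, replace=False)
        kept = [kept[i] for i in sorted(idx)]
    median_units = float(np.median([l.repeat_units for l in kept]))
    return LocusSet(kept, label=candidates.label or "control"), median_units


def compare_sets(
    fsfs_stats: list[WindowStat],
    control_stats: list[WindowStat],
    feature: str = "",
) -> SetComparison:
    """Two-sided Wilcoxon rank-sum comparison of fragile-site vs control windows.

    Exact p for small tie-free samples, normal approximation with
    continuity correction otherwise. Loci without coverage (NaN) are
    dropped and counted. All-tied inputs give p = 1.
    """
    x = np.array([s.value for s in fsfs_stats], dtype=float)
    y = np.array([s.value for s in control_stats], dtype=float)
    n_dropped = int(np.isnan(x).sum() + np.isnan(y).sum())
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("both sets must be non-empty after dropping uncovered loci")
    hw = fsfs_stats[0].half_width if fsfs_stats else 0
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return SetComparison(feature, hw, 1.0, 0, x.size, y.size, n_dropped)
    tie_free = len(np.unique(pooled)) == pooled.size
    method = "exact" if (tie_free and max(x.size, y.size) <= 25) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    direction = int(np.sign(np.median(x) - np.median(y)))
    return SetComparison(feature, hw, float(res.pvalue), direction, x.size, y.size, n_dropped)


def boundary_density(
    ctcf_sites: LocusSet,
    cpg_islands: LocusSet,
    loci: LocusSet,
    window: int = 100_000,
) -> list[tuple[str, int, int]]:
    """Per-locus counts of CTCF sites and CpG islands within a centered window.

    A feature is counted when its midpoint falls in the window of total
    width ``window`` centered on the locus.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    half = window // 2
    out = []
    for locus in loci.loci:
        lo, hi = locus.center - half, locus.center + half
        n_ctcf = sum(1 for f in ctcf_sites.loci
                     if f.chrom == locus.chrom and lo <= (f.start + f.end) // 2 < hi)
        n_cpg = sum(1 for f in cpg_islands.loci
                    if f.chrom == locus.chrom and lo <= (f.start + f.end) // 2 < hi)
        out.append((locus.id, n_ctcf, n_cpg))
    return out


def bh_adjust(p_values: list[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values (emitted alongside raw ones)."""
    return list(stats.false_discovery_control(np.asarray(p_values, dtype=float)))
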