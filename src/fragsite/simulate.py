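"""Synthetic measurement generators for every pipeline stage.

Each generator emulates the statistical structure of one laboratory
measurement so the full analysis is testable without external data:

* metaphase break scoring — each scored metaphase breaks with the
  fragility frequency, at most once, on one homolog; break positions are
  drawn from an interval-mass profile and blurred with Gaussian
  positional noise before per-probe telomeric/spanning/centromeric
  classification;
* fluctuation cultures — per-division breakage events whose descendants
  are all mutant, giving the jackpot-skewed Luria–Delbrück distribution;
* gel lanes — band migration as a (log-)linear function of fragment size
  plus Gaussian distance noise, intensity proportional to molar abundance
  times length (mass detection);
* MNase dose series — per-allele logistic intensity decay with a larger
  half-maximal dose for the resistant allele;
* feature tracks — binned white noise with a planted mean shift inside
  windows around test loci;
* count tables — binomial MN/NBud draws per condition.

All generators are deterministic for a fixed seed. A single global seed
fans out to per-generator substreams by fixed offsets (`substream`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fish import ProbeObservation, ProbePanel, classify_probe_signal
from .features import FeatureTrack, Locus, LocusSet
from .mnase import MNaseSeries, logistic_decay
from .sizing import GelLane
from .stats import CountTable, FluctuationExperiment

__all__ = [
    "TrueBreakageProfile",
    "SEED_OFFSETS",
    "substream",
    "simulate_metaphase_breaks",
    "simulate_fluctuation_cultures",
    "simulate_gel_lane",
    "simulate_mnase_series",
    "simulate_feature_tracks",
    "simulate_count_tables",
    "simulate_control_loci",
    "default_panel",
    "default_profile",
]

#: Fixed per-generator seed offsets so one run seed fans out reproducibly.
SEED_OFFSETS = {
    "breaks": 101,
    "fluctuation": 211,
    "gel": 307,
    "mnase": 401,
    "tracks": 503,
    "counts": 601,
    "controls": 701,
}


def substream(seed: int, generator: str) -> int:
    """Derive the per-generator seed from a global run seed."""
    return (int(seed) * 1000 + SEED_OFFSETS[generator]) % (2**31 - 1)


@dataclass(frozen=True)
class TrueBreakageProfile:
    """Ground-truth break-position distribution: interval masses on one arm."""

    chrom: str
    intervals: tuple[tuple[int, int], ...]
    masses: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.masses) or not self.intervals:
            raise ValueError("need equally many non-empty intervals and masses")
        m = np.asarray(self.masses, dtype=float)
        if np.any(m < 0):
            raise ValueError("masses must be non-negative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")
        ivs = sorted(self.intervals)
        if ivs != list(self.intervals):
            raise ValueError("intervals must be sorted by start")
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if e1 > s2:
                raise ValueError("intervals must be non-overlapping")
        for s, e in ivs:
            if s >= e:
                raise ValueError("intervals must be half-open with start < end")


def simulate_metaphase_breaks(
    profile: TrueBreakageProfile,
    panel: ProbePanel,
    n_metaphases: int,
    fragility_freq: float,
    resolution_bp: float,
    seed: int,
    tolerance_bp: int = 0,
) -> tuple[dict[str, ProbeObservation], list[int]]:
    """Score simulated metaphases against a probe panel.

    Each metaphase carries a break with probability ``fragility_freq`` (at
    most one, on one homolog). The break position is drawn uniformly
    within an interval chosen by its mass, then observed through Gaussian
    positional blur of sd ``resolution_bp`` before classification against
    every probe. Returns per-probe observations and the true (unblurred)
    break positions.
    """
    if not 0.0 <= fragility_freq <= 1.0:
        raise ValueError("fragility_freq must lie in [0, 1]")
    if resolution_bp < 0:
        raise ValueError("resolution_bp must be >= 0")
    rng = np.random.default_rng(seed)
    counts = {p.name: [0, 0, 0] for p in panel.probes}  # tel, span, cen
    kinds = ("telomeric", "spanning", "centromeric")
    true_breaks: list[int] = []
    starts = np.array([iv[0] for iv in profile.intervals])
    widths = np.array([iv[1] - iv[0] for iv in profile.intervals])
    masses = np.asarray(profile.masses)
    for _ in range(n_metaphases):
        if rng.random() >= fragility_freq:
            continue
        i = rng.choice(len(masses), p=masses)
        pos = int(starts[i] + rng.integers(0, widths[i]))
        true_breaks.append(pos)
        observed = pos + (rng.normal(0.0, resolution_bp) if resolution_bp > 0 else 0.0)
        observed = max(int(round(observed)), 0)
        for probe in panel.probes:
            kind = classify_probe_signal(observed, probe, tolerance_bp=tolerance_bp,
                                         arm=panel.arm)
            counts[probe.name][kinds.index(kind)] += 1
    obs = {
        pid: ProbeObservation(pid, n_telomeric=c[0], n_spanning=c[1], n_centromeric=c[2])
        for pid, c in counts.items()
    }
    return obs, true_breaks


def simulate_fluctuation_cultures(
    rate: float, n_cultures: int, n_final: int, seed: int
) -> FluctuationExperiment:
    """Luria–Delbrück branching simulation of parallel cultures.

    Each culture grows 1 → n_final cells through n_final - 1 divisions; a
    breakage event occurs at each division with probability ``rate`` and
    all descendants of the affected cell are mutant. A cell born at the
    j-th division (population j → j+1) leaves ~n_final/(j+1) descendants,
    which produces the characteristic jackpot-skewed mutant counts.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate > 1:
        raise ValueError("rate is a per-division probability and cannot exceed 1")
    if n_final < 1:
        raise ValueError("n_final must be >= 1")
    rng = np.random.default_rng(seed)
    n_final = int(n_final)
    counts = np.zeros(n_cultures)
    if rate > 0 and n_final > 1:
        n_events = rng.binomial(n_final - 1, rate, size=n_cultures)
        for c in range(n_cultures):
            if n_events[c] == 0:
                continue
            j = rng.integers(1, n_final, size=n_events[c])  # division index
            clones = np.round(n_final / (j + 1)).astype(np.int64)
            counts[c] = min(int(clones.sum()), n_final)
    return FluctuationExperiment(counts=counts, n_final=float(n_final))


def simulate_gel_lane(
    ladder: list[tuple[float, float]],
    fragments: list[tuple[float, float]],
    migration_model: str = "linear",
    noise_sd: float = 0.0,
    seed: int = 0,
    intensity_mode: str = "mass",
    sample: str = "sim",
) -> GelLane:
    """Render fragments as gel bands under a ladder-implied migration model.

    ``ladder`` is (distance_mm, size_bp) markers, strictly decreasing in
    size with distance; the migration model (distance as an affine
    function of size or of log size) is fitted to the markers, so a
    fragment matching a marker's size lands at that marker's distance when
    noiseless. ``fragments`` are (size_bp, relative_abundance) pairs; band
    intensity is abundance x size under mass detection (default) or plain
    abundance under 'molar'.
    """
    if migration_model not in ("linear", "log-linear"):
        raise ValueError("migration_model must be 'linear' or 'log-linear'")
    if len(ladder) < 2:
        raise ValueError("need >=2 ladder markers")
    ladder = sorted(ladder, key=lambda m: m[0])
    dist = np.array([m[0] for m in ladder], dtype=float)
    size = np.array([m[1] for m in ladder], dtype=float)
    if np.any(np.diff(size) >= 0):
        raise ValueError("ladder marker sizes must strictly decrease with distance")
    x = np.log(size) if migration_model == "log-linear" else size
    slope, intercept = np.polyfit(x, dist, 1)
    rng = np.random.default_rng(seed)
    bands = []
    for frag_size, abundance in fragments:
        if frag_size <= 0 or abundance < 0:
            raise ValueError("fragment sizes must be positive and abundances >= 0")
        xf = np.log(frag_size) if migration_model == "log-linear" else frag_size
        d = slope * xf + intercept
        if noise_sd > 0:
            d += rng.normal(0.0, noise_sd)
        intensity = abundance * frag_size if intensity_mode == "mass" else abundance
        bands.append((max(float(d), 0.0), float(intensity)))
    return GelLane(bands=bands, sample=sample)


def simulate_mnase_series(
    protection: dict[str, tuple[float, float]],
    doses: list[float],
    seed: int = 0,
    noise_sd: float = 0.02,
    intensity0: float = 100.0,
) -> MNaseSeries:
    """Per-allele band intensities decaying logistically with MNase dose.

    ``protection`` maps allele → (half-max dose, slope); the resistant
    (expanded) allele carries the larger half-max. Multiplicative Gaussian
    noise of sd ``noise_sd`` (relative to the starting intensity) is added
    at non-zero doses; intensities are clipped at zero.
    """
    doses_arr = np.asarray(sorted(doses), dtype=float)
    if 0.0 not in doses_arr:
        raise ValueError("dose series must include dose 0")
    rng = np.random.default_rng(seed)
    intensities = {}
    for allele, (half_max, slope) in protection.items():
        if half_max <= 0 or slope <= 0:
            raise ValueError(f"allele {allele}: half_max and slope must be positive")
        clean = intensity0 * logistic_decay(doses_arr, half_max, slope)
        noise = np.where(doses_arr > 0, rng.normal(0.0, noise_sd * intensity0,
                                                   size=doses_arr.shape), 0.0)
        intensities[allele] = np.clip(clean + noise, 0.0, None)
    return MNaseSeries(doses=doses_arr, intensities=intensities)


def simulate_feature_tracks(
    loci: LocusSet,
    control_loci: LocusSet,
    effect: float,
    half_width: int,
    seed: int,
    bin_size: int = 10_000,
    noise_sd: float = 1.0,
    chrom_sizes: dict[str, int] | None = None,
) -> FeatureTrack:
    """A binned white-noise track with ``effect`` added inside test-locus windows.

    Control loci receive no shift (window mean expectation 0), so the
    downstream rank-sum comparison is calibrated under effect = 0.
    """
    if not loci.disjoint_from(control_loci):
        raise ValueError("test and control loci must be disjoint")
    if half_width <= 0 or bin_size <= 0:
        raise ValueError("half_width and bin_size must be positive")
    rng = np.random.default_rng(seed)
    if chrom_sizes is None:
        chrom_sizes = {}
        for l in [*loci.loci, *control_loci.loci]:
            need = l.center + 2 * half_width + bin_size
            chrom_sizes[l.chrom] = max(chrom_sizes.get(l.chrom, 0), need)
    data = {}
    for chrom in sorted(chrom_sizes):
        n_bins = int(np.ceil(chrom_sizes[chrom] / bin_size))
        starts = np.arange(n_bins, dtype=np.int64) * bin_size
        ends = starts + bin_size
        values = rng.normal(0.0, noise_sd, size=n_bins)
        for l in loci.loci:
            if l.chrom != chrom:
                continue
            mids = starts + bin_size // 2
            inside = (mids >= l.center - half_width) & (mids < l.center + half_width)
            values[inside] += effect
        data[chrom] = (starts, ends, values)
    return FeatureTrack(data)


def simulate_count_tables(
    p_case: float, p_control: float, n_cells: int, seed: int,
    categories: tuple[str, ...] = ("MN", "NBud"),
) -> tuple[CountTable, CountTable]:
    """Binomial event draws per category for a case and a control condition."""
    for p in (p_case, p_control):
        if not 0.0 <= p <= 1.0:
            raise ValueError("probabilities must lie in [0, 1]")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    rng = np.random.default_rng(seed)
    case = CountTable(
        n_cells=n_cells,
        events={c: int(rng.binomial(n_cells, p_case)) for c in categories},
        condition="case",
    )
    control = CountTable(
        n_cells=n_cells,
        events={c: int(rng.binomial(n_cells, p_control)) for c in categories},
        condition="control",
    )
    return case, control


def simulate_control_loci(
    n: int,
    seed: int,
    chrom: str = "chrS",
    spacing: int = 2_000_000,
    min_units: float = 4.5,
    median_excess: float = 4.2,
    label: str = "control_nongenic",
    offset: int = 1_000_000,
) -> LocusSet:
    """Control repeat loci with unit counts ``min_units + Exp(mean)``.

    The exponential mean is ``median_excess / ln 2`` so the median unit
    count of loci passing the > min_units filter is min_units +
    median_excess (8.7 with the defaults, the length-matching condition
    for the control set).
    """
    rng = np.random.default_rng(seed)
    units = min_units + rng.exponential(median_excess / np.log(2), size=n)
    loci = [
        Locus(chrom, offset + i * spacing, offset + i * spacing + 100,
              id=f"ctrl_{i}", repeat_units=float(units[i]))
        for i in range(n)
    ]
    return LocusSet(loci, label=label)


def default_panel() -> ProbePanel:
    """A seven-probe 9p21-style panel (synthetic coordinates, telomere→centromere)."""
    from .io import GenomicInterval

    coords = [
        ("probe1", 19_900_000, 20_070_000),
        ("probe2", 21_950_000, 22_120_000),
        ("probe3", 26_200_000, 26_370_000),
        ("probe4", 27_500_000, 27_670_000),  # contains the repeat locus
        ("probe5", 28_600_000, 28_770_000),
        ("probe6", 30_500_000, 30_670_000),
        ("probe7", 32_400_000, 32_570_000),
    ]
    return ProbePanel(
        tuple(GenomicInterval("chr9", s, e, name=n) for n, s, e in coords), arm="p"
    )


def default_profile() -> TrueBreakageProfile:
    """A three-interval ground truth: a dominant core flanked by minor zones.

    Masses (0.10, 0.83, 0.07) emulate a fragility core carrying >=83% of
    breaks with minor telomeric and centromeric breakage, placed strictly
    between panel probes so the inferred inter-probe masses are comparable
    to truth.
    """
    return TrueBreakageProfile(
        chrom="chr9",
        intervals=((22_120_000, 26_200_000),
                   (26_370_000, 27_500_000),
                   (28_770_000, 30_500_000)),
        masses=(0.10, 0.83, 0.07),
    )
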