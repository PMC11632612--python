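"""Southern-blot repeat sizing from gel migration ladders.

Band migration distances are converted to fragment sizes through a
least-squares calibration against molecular-weight markers (size or
log-size regressed on distance), then to repeat counts by subtracting the
enzyme-specific restriction flanks and dividing by the 6-bp GGGGCC unit.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DigestSpec",
    "DIGESTS",
    "LadderCalibration",
    "GelLane",
    "RepeatSizeEstimate",
    "MosaicismSummary",
    "fit_ladder",
    "size_band",
    "bp_to_repeats",
    "repeats_to_bp",
    "summarize_mosaicism",
]


@dataclass(frozen=True)
class DigestSpec:
    """Restriction digest releasing the repeat with fixed flanking lengths."""

    enzyme_pair: str
    flank_up: int
    flank_down: int
    repeat_unit: int = 6

    def __post_init__(self) -> None:
        if self.flank_up < 0 or self.flank_down < 0:
            raise ValueError("flanks must be >= 0")
        if self.repeat_unit <= 0:
            raise ValueError("repeat_unit must be positive")

    @property
    def flank_total(self) -> int:
        return self.flank_up + self.flank_down


#: Named digests used for sizing the C9orf72 GGGGCC expansion: upstream and
#: downstream flank lengths (bp) left around the repeat tract.
DIGESTS: dict[str, DigestSpec] = {
    "EcoRI_BamHI": DigestSpec("EcoRI_BamHI", flank_up=697, flank_down=1714),
    "AflII_PciI": DigestSpec("AflII_PciI", flank_up=404, flank_down=689),
    "XbaI_XbaI": DigestSpec("XbaI_XbaI", flank_up=1751, flank_down=608),
}


@dataclass(frozen=True)
class LadderCalibration:
    """Fitted migration-distance → fragment-size mapping.

    model 'linear' regresses size on distance; 'log-linear' regresses
    log(size) on distance (gel migration is typically log-linear in size,
    but the plain linear fit is the default read-out convention here).
    """

    markers: tuple[tuple[float, float], ...]  # (distance_mm, size_bp)
    model: str
    slope: float
    intercept: float
    residual_sd: float

    @property
    def distance_range(self) -> tuple[float, float]:
        d = [m[0] for m in self.markers]
        return min(d), max(d)


@dataclass
class GelLane:
    """Quantified bands of one gel lane: (distance_mm, intensity) pairs."""

    bands: list[tuple[float, float]]
    sample: str = ""
    digest: str | None = None

    def __post_init__(self) -> None:
        for d, i in self.bands:
            if d < 0 or i < 0:
                raise ValueError("band distances and intensities must be >= 0")


@dataclass(frozen=True)
class RepeatSizeEstimate:
    fragment_bp: float
    repeats: int
    digest: DigestSpec


@dataclass(frozen=True)
class MosaicismSummary:
    min_repeats: int
    max_repeats: int
    modal_repeats: int
    estimates: tuple[RepeatSizeEstimate, ...]


def fit_ladder(
    markers: list[tuple[float, float]], model: str = "linear"
) -> LadderCalibration:
    """Least-squares fit of marker size (or log size) on migration distance."""
    if model not in ("linear", "log-linear"):
        raise ValueError("model must be 'linear' or 'log-linear'")
    if len(markers) < 2:
        raise ValueError("need >=2 ladder markers")
    markers = sorted(markers, key=lambda m: m[0])
    dist = np.array([m[0] for m in markers], dtype=float)
    size = np.array([m[1] for m in markers], dtype=float)
    if len(np.unique(dist)) != len(dist):
        raise ValueError("duplicate marker distances")
    if np.any(np.diff(size) >= 0):
        raise ValueError("marker sizes must strictly decrease with distance")
    y = np.log(size) if model == "log-linear" else size
    slope, intercept = np.polyfit(dist, y, 1)
    resid = y - (slope * dist + intercept)
    dof = max(len(dist) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return LadderCalibration(
        markers=tuple((float(d), float(s)) for d, s in markers),
        model=model,
        slope=float(slope),
        intercept=float(intercept),
        residual_sd=residual_sd,
    )


def size_band(cal: LadderCalibration, distance: float) -> float:
    """Predict fragment size (bp) at a migration distance; warns on extrapolation."""
    lo, hi = cal.distance_range
    if not lo <= distance <= hi:
        warnings.warn(
            f"distance {distance} mm outside marker range [{lo}, {hi}] mm; extrapolating",
            stacklevel=2,
        )
    pred = cal.slope * distance + cal.intercept
    if cal.model == "log-linear":
        return float(math.exp(pred))
    if pred <= 0:
        raise ValueError(f"predicted non-positive size ({pred:.1f} bp) at {distance} mm")
    return float(pred)


def bp_to_repeats(fragment_bp: float, digest: DigestSpec) -> int:
    """Repeat count from fragment size: round((bp - flanks) / unit), >= 0.

    Fragments within half a repeat unit below the flank total (calibration
    round-off around a zero-repeat fragment) clip to 0; anything smaller is
    an error.
    """
    if fragment_bp < digest.flank_total - digest.repeat_unit / 2:
        raise ValueError(
            f"fragment ({fragment_bp:.0f} bp) smaller than digest flanks "
            f"({digest.flank_total} bp for {digest.enzyme_pair})"
        )
    return max(int(round((fragment_bp - digest.flank_total) / digest.repeat_unit)), 0)


def repeats_to_bp(repeats: int, digest: DigestSpec) -> int:
    """Fragment size produced by a digest for a given repeat count."""
    if repeats < 0:
        raise ValueError("repeats must be >= 0")
    return digest.flank_total + digest.repeat_unit * repeats


def summarize_mosaicism(
    lane: GelLane, cal: LadderCalibration, digest: DigestSpec
) -> MosaicismSummary:
    """Per-band repeat estimates and the modal band of a (possibly smeared) lane.

    The mode is the highest-intensity band; intensity ties break toward the
    larger fragment (conservative for expansions).
    """
    if not lane.bands:
        raise ValueError("lane has no bands")
    estimates = []
    for distance, intensity in lane.bands:
        bp = size_band(cal, distance)
        estimates.append((RepeatSizeEstimate(bp, bp_to_repeats(bp, digest), digest), intensity))
    reps = [e.repeats for e, _ in estimates]
    modal = max(estimates, key=lambda t: (t[1], t[0].repeats))[0].repeats
    return MosaicismSummary(
        min_repeats=min(reps),
        max_repeats=max(reps),
        modal_repeats=modal,
        estimates=tuple(e for e, _ in estimates),
    )
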