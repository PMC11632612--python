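"""Chromosomal-instability statistics.

Covers the count-based comparisons used for micronucleus (MN) / nuclear bud
(NBud) scoring, sister-chromatid-exchange (SCE) group comparisons and
chromosome-arm enrichment, and Luria–Delbrück fluctuation analysis of
breakage rates in the yeast artificial-chromosome end-loss assay.

MN and NBud events are pooled before testing because both arise from the
same breakage phenomenon; the pooled 2x2 table (events vs event-free cells)
is tested with a two-sided Fisher exact test. Breakage rates come from the
Lea–Coulson method of the median: the median mutant count r solves

    r / m - ln(m) = 1.24

for m, the expected number of breakage events per culture, and the rate is
m divided by the final cell count. A Ma–Sandri–Sarkar style maximum-
likelihood estimate over the Luria–Delbrück distribution is available as an
alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CountTable",
    "SCESample",
    "FluctuationExperiment",
    "RateEstimate",
    "mn_nbud_test",
    "sce_compare",
    "arm_enrichment",
    "lea_coulson_rate",
    "rate_fold_change",
    "luria_delbruck_pmf",
]

LEA_COULSON_CONSTANT = 1.24


@dataclass(frozen=True)
class CountTable:
    """Scored cells and per-category event counts for one condition."""

    n_cells: int
    events: dict[str, int]
    condition: str = ""

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        for cat, k in self.events.items():
            if not 0 <= k <= self.n_cells:
                raise ValueError(f"category {cat}: events must lie in [0, n_cells]")

    def pooled(self, categories: tuple[str, ...]) -> int:
        return sum(self.events[c] for c in categories)


@dataclass
class SCESample:
    """Per-metaphase SCE counts, optionally with per-arm counts."""

    counts: np.ndarray
    arm_counts: np.ndarray | None = None
    arm_fraction: float | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("SCE counts must be >= 0")
        if self.arm_fraction is not None and not 0.0 < self.arm_fraction < 1.0:
            raise ValueError("arm_fraction must lie in (0, 1)")


@dataclass
class FluctuationExperiment:
    """Mutant counts per parallel culture, with the final cell count."""

    counts: np.ndarray
    n_final: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValueError("mutant counts must be >= 0")
        if self.n_final < 1:
            raise ValueError("n_final must be >= 1")


@dataclass(frozen=True)
class RateEstimate:
    """Expected events per culture (m) and per-cell rate m / n_final."""

    m: float
    rate: float
    n_cultures: int
    censored: bool = False
    method: str = "median"


@dataclass(frozen=True)
class TestResult:
    p_value: float
    effect: float
    statistic: float | None = None
    test: str = ""
    per_category: dict | None = None


def mn_nbud_test(
    case: CountTable, control: CountTable, categories: tuple[str, ...] = ("MN", "NBud")
) -> TestResult:
    """Two-sided Fisher exact test on pooled MN+NBud events, case vs control.

    Returns the odds ratio as the effect; per-category Fisher results are
    attached for transparency.
    """
    for t in (case, control):
        missing = [c for c in categories if c not in t.events]
        if missing:
            raise ValueError(f"missing categories {missing} in table {t.condition!r}")
    k1, k2 = case.pooled(categories), control.pooled(categories)
    table = [[k1, case.n_cells - k1], [k2, control.n_cells - k2]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    per_cat = {}
    for c in categories:
        t = [[case.events[c], case.n_cells - case.events[c]],
             [control.events[c], control.n_cells - control.events[c]]]
        o_c, p_c = stats.fisher_exact(t, alternative="two-sided")
        per_cat[c] = {"odds_ratio": float(o_c), "p_value": float(p_c)}
    return TestResult(p_value=float(p), effect=float(odds), test="fisher", per_category=per_cat)


def sce_compare(
    group_a: SCESample,
    group_b: SCESample,
    test: str = "t",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> TestResult:
    """Two-sided two-sample comparison of per-metaphase SCE counts.

    ``test='t'`` uses Student's t; ``'wilcoxon'`` uses the rank-sum test.
    Degenerate variance under the t-test falls back to an exact/Monte-Carlo
    permutation test with a warning. The effect is the fold-change of
    means (a / b).
    """
    a, b = group_a.counts, group_b.counts
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >=2 metaphases per group")
    mean_b = b.mean()
    fold = float(a.mean() / mean_b) if mean_b > 0 else float("inf")
    if test == "wilcoxon":
        stat, p = _ranksum(a, b)
        return TestResult(p_value=p, effect=fold, statistic=stat, test="wilcoxon")
    if test != "t":
        raise ValueError("test must be 't' or 'wilcoxon'")
    pooled = np.concatenate([a, b])
    if np.var(pooled) == 0:
        return TestResult(p_value=1.0, effect=1.0, statistic=0.0, test="permutation")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("degenerate within-group variance; using permutation test", stacklevel=2)
        res = stats.permutation_test(
            (a, b),
            lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            n_resamples=n_permutations,
            alternative="two-sided",
            rng=seed,
            vectorized=True,
        )
        return TestResult(p_value=float(res.pvalue), effect=fold,
                          statistic=float(res.statistic), test="permutation")
    stat, p = stats.ttest_ind(a, b)
    return TestResult(p_value=float(p), effect=fold, statistic=float(stat), test="t")


def _ranksum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    if np.var(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    method = "exact" if (max(len(a), len(b)) <= 25 and _no_ties(a, b)) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _no_ties(a: np.ndarray, b: np.ndarray) -> bool:
    pooled = np.concatenate([a, b])
    return len(np.unique(pooled)) == len(pooled)


def arm_enrichment(arm_count: int, total_count: int, arm_fraction: float) -> float:
    """One-sided exact binomial tail P(X >= arm_count | total, arm_fraction).

    Tests whether events (e.g. SCEs) are enriched on one chromosome arm
    relative to its physical length fraction of the scored genome.
    """
    if not 0.0 < arm_fraction < 1.0:
        raise ValueError("arm_fraction must lie in (0, 1)")
    if not 0 <= arm_count <= total_count:
        raise ValueError("require 0 <= arm_count <= total_count")
    return float(stats.binom.sf(arm_count - 1, total_count, arm_fraction))


def _lea_coulson_m(median_count: float) -> float:
    # root of r/m - ln(m) = 1.24; the LHS is strictly decreasing in m on (0, inf)
    r = float(median_count)
    g = lambda m: r / m - np.log(m) - LEA_COULSON_CONSTANT

    lo, hi = 1e-12, max(4.0 * r, 1.0)
    while g(hi) > 0:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("Lea-Coulson root not bracketable")
    m = optimize.brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return float(m)


def luria_delbruck_pmf(m: float, max_count: int) -> np.ndarray:
    """Luria–Delbrück mutant-count pmf p_0..p_max via the Ma–Sandri–Sarkar recursion."""
    p = np.zeros(max_count + 1)
    p[0] = np.exp(-m)
    for r in range(1, max_count + 1):
        p[r] = (m / r) * np.sum(p[:r] / (r - np.arange(r) + 1.0))
    return p


def _mss_ml_m(counts: np.ndarray) -> float:
    max_count = int(counts.max())

    def nll(log_m: float) -> float:
        pmf = luria_delbruck_pmf(np.exp(log_m), max_count)
        return -np.sum(np.log(np.maximum(pmf[counts.astype(int)], 1e-300)))

    res = optimize.minimize_scalar(nll, bounds=(-12, 12), method="bounded")
    return float(np.exp(res.x))


def lea_coulson_rate(exp: FluctuationExperiment, method: str = "median") -> RateEstimate:
    """Breakage/mutation rate per cell from a fluctuation experiment.

    ``method='median'`` (default) solves the Lea–Coulson median equation;
    ``'mss'`` maximizes the Luria–Delbrück likelihood. A zero median yields
    the censored upper bound m = ln 2 (the m at which half the cultures are
    expected to carry no event).
    """
    if len(exp.counts) < 5:
        raise ValueError("need >=5 parallel cultures")
    if method == "mss":
        if np.all(exp.counts == 0):
            return RateEstimate(m=np.log(2), rate=np.log(2) / exp.n_final,
                                n_cultures=len(exp.counts), censored=True, method=method)
        m = _mss_ml_m(exp.counts)
        return RateEstimate(m=m, rate=m / exp.n_final, n_cultures=len(exp.counts), method=method)
    if method != "median":
        raise ValueError("method must be 'median' or 'mss'")
    r = float(np.median(exp.counts))
    if r == 0:
        m = float(np.log(2))
        return RateEstimate(m=m, rate=m / exp.n_final, n_cultures=len(exp.counts),
                            censored=True, method=method)
    m = _lea_coulson_m(r)
    return RateEstimate(m=m, rate=m / exp.n_final, n_cultures=len(exp.counts), method=method)


@dataclass(frozen=True)
class FoldChange:
    fold: float
    ci_low: float
    ci_high: float
    censored: bool = False


def rate_fold_change(
    a: FluctuationExperiment,
    b: FluctuationExperiment,
    n_boot: int = 1000,
    seed: int = 0,
    method: str = "median",
) -> FoldChange:
    """Rate ratio a/b with a percentile bootstrap CI (resampling cultures).

    A zero (censored) denominator rate marks the fold as censored.
    """
    rng = np.random.default_rng(seed)
    est_a = lea_coulson_rate(a, method=method)
    est_b = lea_coulson_rate(b, method=method)
    if est_b.rate == 0:
        return FoldChange(float("inf"), float("nan"), float("nan"), censored=True)
    fold = est_a.rate / est_b.rate
    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = lea_coulson_rate(
            FluctuationExperiment(rng.choice(a.counts, size=len(a.counts)), a.n_final),
            method=method,
        ).rate
        rb = lea_coulson_rate(
            FluctuationExperiment(rng.choice(b.counts, size=len(b.counts)), b.n_final),
            method=method,
        ).rate
        boots[i] = ra / rb if rb > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [2.5, 97.5]) if boots.size else (np.nan, np.nan)
    return FoldChange(float(fold), float(lo), float(hi),
                      censored=est_a.censored or est_b.censored)
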