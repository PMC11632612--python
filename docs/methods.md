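# Methods

This note documents the models, estimators and numerical choices behind
`fragsite`, what the synthetic-data generators do and do not emulate, and
the known limitations of each procedure.

## FISH breakage-zone inference

**Model.** A folate-sensitive fragile site expresses on metaphase
chromosomes as a gap or break whose position is scored relative to
locus-specific FISH probes. For a probe at position $x_i$ along a p-arm
(telomere at coordinate 0), a signal scored *centromeric* of the break
means the break lies telomeric of the probe. The centromeric-signal
fraction of probe $i$,

$$F_i = \frac{n_{\mathrm{cen},i} + s \cdot n_{\mathrm{span},i}}{n_i},$$

therefore samples the cumulative distribution of break positions at
$x_i$. Spanning signals are apportioned a fraction $s$ (default 0.5) to
each side; their split is not knowable from orientation counts alone, so
$s$ is exposed and the result should be (and is, in tests) insensitive to
it at the tolerance of interest. Interval breakage masses are first
differences of $F$ between adjacent probes, with the residual mass in the
two flanking end intervals; interval boundaries are probe midpoints.

**Isotonic step.** $F$ is a CDF sampled with multinomial noise, so its
estimates can violate monotonicity. With `enforce_monotone=True` (the
default) the estimates are projected onto the non-decreasing cone by
count-weighted pool-adjacent-violators (the weighted least-squares
isotonic projection; verified in tests against a brute-force constrained
quadratic program). Without it, violations emit a warning and negative
masses are clipped at zero and renormalized.

**Assumptions.** At most one break per metaphase, on one homolog
(heterozygous expansions express fragility on the expanded homolog only);
probes scored in different metaphase subsets are independent marginal
samples of the same break distribution; positional observation error is
Gaussian on the break coordinate.

**Fragility frequency and significance.** Frequency $k/n$ carries an
exact two-sided Clopper–Pearson interval (default 99%). Significance
against background uses the one-sided exact binomial tail
$P(X \ge k \mid n, p_0)$. The default background $p_0 = 0.008$ breaks per
metaphase per band is a *reconstruction*: it is the rate under which the
classical diagnostic rule — 3 (5) positives in 100 metaphases give 95%
(99%) confidence — holds; it is a configuration parameter, not a measured
value.

**Zone geometry.** `FragileZone` records the mapped breakage extents
around a fragility core in Mb; the bundled `FRA9A_ZONE` constant carries
the 2.0 Mb telomeric / 6.2 Mb centromeric extents (8.2 Mb span) of the
9p21 zone.

## Repeat sizing from gel ladders

Marker size (model `linear`) or log-size (`log-linear`) is regressed on
migration distance by least squares; the fitted line converts band
distances to fragment sizes, warning outside the marker range. Gel
migration is physically closer to log-linear in size; the plain linear
fit is nevertheless the default read-out convention here, and both models
are tested. Repeat counts are
`round((fragment − flank_up − flank_down) / 6)` with the three named
digests (EcoRI/BamHI 697/1714, AflII/PciI 404/689, XbaI/XbaI 1751/608 bp
flanks). Fragments up to half a unit below the flank total clip to zero
repeats (calibration round-off); smaller fragments are an error. Mosaic
smears are represented as discretized band lists — no deconvolution; the
modal band is the highest-intensity one, ties breaking toward the larger
fragment (conservative for expansions).

## MNase accessibility

Band intensities per allele are normalized to the zero-dose lane, making
the fraction undigested exactly 1 at dose 0. The dose–response summary is
a Hill-type decay $f(d) = 1/(1 + (d/h)^s)$ fitted by nonlinear least
squares ($h$ = half-maximal dose in MNase units, bounds $h \in [10^{-9},
10^9]$, $s \in [0.05, 50]$, initial $h$ at the first 0.5-crossing). The
densitometry itself fits no model, so a model-free trapezoidal
area-under-curve (mean fraction over the dose range) is always emitted
alongside. Allele comparisons report pointwise ratios (denominator
floored at a configurable $\varepsilon = 10^{-3}$ with a censoring flag
rather than infinities), the half-max ratio and the AUC ratio.

Boundary mapping takes fractions of full-length fragment retained at
restriction sites stored as signed distances from the repeat edges
(upstream negative). Per direction, the resistance extent is the interval
(farthest site with retention > threshold, nearest site beyond it with
retention ≤ threshold]; the default threshold of 0.1 of starting-material
signal operationalizes "some full-length fragment still inaccessible" and
is configurable. All-retained and all-lost patterns are censored rather
than extrapolated; non-monotone retention warns and follows the
farthest-retained rule.

## Fluctuation analysis

Rates come from the Lea–Coulson method of the median: the median mutant
count $\tilde r$ solves $\tilde r/m - \ln m = 1.24$ for the expected
events per culture $m$ (bracketed Brent root-finding, residual < 1e−10;
the left side is strictly decreasing in $m$ so the root is unique), and
the rate is $m/N_\mathrm{final}$. A zero median yields the censored upper
bound $m = \ln 2$ (the $m$ at which half the cultures carry no event
under Poisson event counts). A Ma–Sandri–Sarkar-style maximum-likelihood
estimate over the Luria–Delbrück distribution (pmf by the standard
recursion) is available as `method="mss"`. Plating efficiency is assumed
1 unless dilutions are handled as sample metadata upstream. Rate fold
changes carry percentile bootstrap CIs resampling cultures within each
experiment (percentile rather than BCa, for simplicity; seeds explicit).

## Count statistics

Micronucleus and nuclear-bud events are pooled before testing (both arise
from the same breakage phenomenon) and compared by a two-sided Fisher
exact test on the events / event-free-cells 2×2 table; per-category tests
are attached for transparency. SCE group comparisons default to Student's
t (the convention for this endpoint) with a rank-sum option; degenerate
within-group variance falls back to a permutation test with a warning.
Arm enrichment is the exact binomial tail against the arm's physical
length fraction of the scored genome — that fraction is a user input, and
the binomial-vs-arm-fraction formulation is a documented reconstruction
of the enrichment null.

## Windowed feature comparison

Track values are aggregated as length-weighted means over windows of
half-width 50 kb and 500 kb centered on the floor of the repeat midpoint;
point features (CTCF sites, CpG islands, replication origins) are counted
by midpoint inclusion. Windows clipped at chromosome or coverage ends
average over the covered part only; loci with no coverage are dropped
from the comparison and counted in the report. Control repeats are
filtered to > 4.5 units (reported with their median length, matched at
≈ 8.7 units to the fragile-site set) and optionally subsampled with a
seed. Set comparisons use the two-sided Wilcoxon rank-sum test — exact
for tie-free samples up to n = 25, normal approximation with continuity
correction otherwise; all-tied inputs give p = 1. Raw p-values are the
primary output; Benjamini–Hochberg-adjusted values are emitted alongside
as additive information.

## Synthetic-data generators

The generators reproduce the *statistical structure* of each measurement,
not its physics:

* **Metaphase breaks** — Bernoulli fragility per metaphase (at most one
  break, one homolog), interval chosen by mass, position uniform within
  the interval, Gaussian positional blur before probe classification.
  Defaults: 100-metaphase scoring for frequency examples; 5000 metaphases
  for profile recovery. The default blur sd is 500 kb (a plausible
  metaphase-FISH resolution; not a measured value). The recovery check
  runs at 20 kb blur — an estimator-consistency check requires blur small
  relative to the ≥ 1 Mb inter-probe spacing, since positional blur
  contributes an irreducible bias of order (local density × sd) at each
  probe boundary.
* **Fluctuation cultures** — events Binomial($N-1$, rate) over divisions;
  an event at the $j$-th division leaves $\approx N/(j+1)$ mutant
  descendants (deterministic exponential growth), giving the jackpot
  tail. Study conditions: 30 cultures, $N = 10^7$, rates near $10^{-6}$.
* **Gel lanes** — distance affine in size (or log size) as implied by the
  ladder, Gaussian distance noise, intensity = abundance × length (mass
  detection; molar mode available).
* **MNase series** — logistic intensity decay per allele plus
  multiplicative Gaussian noise (2% of starting intensity by default);
  the resistant allele has the larger half-max (defaults 100 U vs 5 U
  over a 0–200 U dose series).
* **Feature tracks** — 10 kb-binned white noise with the effect added in
  test-locus windows; control windows have expectation 0.
* **Count tables** — independent binomial draws per category per
  condition (≈ 1000 binucleated cells scored per condition).

What passing tests on these generators show: the estimators are
consistent, calibrated (type-I error, CI coverage, null p-value
uniformity) and exact where exactness is claimed, *under the generative
assumptions*. What they do not show: robustness to scorer bias,
densitometric background, non-Gaussian gel distortions, culture-size
variation across replicate cultures, or spatial autocorrelation in real
genomic tracks — none of which the generators model.

## Problem sizes and numerical choices

Simulation sizes used by the test suite and the acceptance script (5000
metaphases; 50 fluctuation experiments × 30 cultures; 2000 replicates for
calibration checks; 100 seeds for dose–response recovery) are the sizes
at which the corresponding statistical guarantees are stated, and run in
seconds on one CPU. All randomness flows from explicit seeds; a single
run seed fans out to per-generator substreams by fixed offsets. Reports
serialize deterministically (sorted keys, no timestamps) and embed the
configuration hash, seed and package version.

## Known limitations

* Breakage-profile resolution is bounded by probe spacing; masses within
  an inter-probe interval are not localized further, and the flanking-end
  intervals depend on the supplied arm bounds.
* The spanning-signal split and the diagnostic background rate are
  conventions, not measurements; both are exposed in configuration.
* The Lea–Coulson median method assumes equal final cell counts and no
  post-plating death; the MSS alternative shares the no-death assumption.
* Boundary mapping reads retention at a single reference dose and
  localizes boundaries only to between-site intervals.
* Window comparisons treat loci as exchangeable; real genomic tracks are
  autocorrelated, so p-values on real data are anti-conservative to an
  unquantified degree.
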