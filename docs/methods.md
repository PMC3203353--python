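# Methods

## Genome binning and z-scores

Chromosomes (hg18 chr1–22, X, Y by default; any chromosome-sizes table is
accepted) are partitioned into contiguous, non-overlapping bins of
`bin_size` bp (default 1 Mb). The final bin of each chromosome truncates
at the chromosome end (ceiling division), bins never span chromosome
boundaries, and the per-chromosome bin lists are concatenated ("strung
together") into one genome-wide sequence of `n` bins — 3091 for hg18 at
1 Mb. An optional `shift` in `[0, bin_size)` inserts a leading partial
bin of exactly that width on every chromosome, displacing all interior
boundaries; detections from several shifted partitions can be merged
(below). Input positions are 1-based; a bin stored as `(start, end)`
covers positions `start+1 .. end`, which doubles as a 0-based half-open
BED interval.

Per-bin VIS counts `C_i` are standardized genome-wide:

    X_i = (C_i − C̄) / SE(C),      SE(C) = sd(C) / √n

with `C̄` and the sample standard deviation taken across all `n` bins.
Standardizing by the standard error of the mean (not the sd) inflates the
scores by `√n ≈ 55.6`; this is the scale on which the default hot-bin
threshold of 422 (the 99.92th percentile of a reference acute-infection
dataset's z-scores) lives, and calibrated thresholds are computed with
linearly interpolated quantiles (numpy/R type 7) so they are reproducible
to the printed digit. Constant count vectors are rejected as degenerate.
A bin-rate variant (`C_i / ΣC_i`, default threshold 0.006 from the same
reference calibration) supports cross-dataset comparison on a
size-normalized scale.

One caveat on scales: the dataset-level clustering statistic "maximum %"
(below) standardizes by the plain per-bin sd, not the SE. An sd-scale
z-score can never exceed `√n`, so on the SE scale the statistic would be
two orders of magnitude larger than its conventional flagging range
(values above 8 indicate strong clustering); the two scales are each
documented where used.

## CIS baseline

A rule `(X kb, Y)` qualifies a region when some X-kb window holds ≥ Y
VIS. Sliding a window 1 bp at a time is equivalent, for point data, to
testing whether Y consecutive sorted VIS span less than the window width
(windows are half-open, so a window of width `w` covers two positions iff
they differ by `< w`); the implementation uses the O(m) consecutive-VIS
form and the test suite checks it against a literal 1 bp sliding scan.
The default definition is ≥3 in 50 kb or ≥4 in 100 kb — either density
triggers a call; qualifying runs from all rules are pooled and
overlapping or VIS-sharing runs merge into maximal disjoint hot-spots
bounded by their outermost member VIS.

## z-threshold detection and hot-spot refinement

Hot-bins are bins whose score (z, rate, or BCP posterior mean) strictly
exceeds the threshold; exact ties are excluded and logged. Maximal runs
of consecutive hot-bins on one chromosome — never bridged across a
non-hot gap — become hot-spots. Each outer boundary then moves to the
VIS nearest to that bin edge, searching both inside and outside the run
(refinement may cross bin boundaries); distances are measured to the
midpoint between the edge's flanking base pairs, so an interior and an
exterior VIS can tie exactly, and ties resolve toward the interior. A
run with no usable VIS keeps its bin edges and is flagged. Hot-spot
statistics: `n_vis` and `pct_vis` (share of the dataset inside the
interval), `size_mb = (end − start)/10⁶`, and `pct_density =
pct_vis/size_mb`.

## Bayesian change-point model

The bin z-scores `X_1..X_n` are modeled with the Barry–Hartigan product
partition model: an unknown partition of the sequence into contiguous
blocks, block means drawn from `N(μ₀, σ₀²/m)` for a block of length `m`,
observations `N(μ_block, σ²)`, and bounded uniform priors on the change
probability `p ∈ (0, p0]` and on the variance ratio
`w = σ²/(σ² + σ₀²) ∈ (0, w0]`. Defaults: `p0 = w0 = 0.2`. Integrating
the block means, the grand mean (flat prior) and the error variance
(`1/σ²` prior) leaves a partition posterior

    K(ρ) ∝ [∫₀^p0 p^c (1−p)^{n−1−c} dp] · [∫₀^w0 w^{c/2} (W + wB)^{−(n−1)/2} dw]

where `c` is the number of change points and `W`, `B` are the within- and
between-block sums of squares (`W + B` = total SS). A Gibbs sweep
resamples every change indicator from the conditional odds
`K(ρ_i = 1)/K(ρ_i = 0)`; toggling one indicator only changes the two
adjacent blocks, so each update costs O(1) via prefix sums plus the
integral evaluations. The `p`-integrals are tabulated once per fit as
regularized incomplete beta functions. The `w`-integral has the closed
form

    ∫₀^w0 w^{c/2}(W+wB)^{−(n−1)/2} dw
      = (W/B)^{c/2+1} W^{−(n−1)/2} B(β₁, β₂) I_{u₀}(β₁, β₂),
    β₁ = c/2 + 1,  β₂ = (n−c−3)/2,  u₀ = Bw0/(W + Bw0)

used whenever `β₂ > 0`, with a log-space midpoint quadrature covering the
corner `c ≥ n−3` and a separable form when `B ≈ 0`. The sampler kernel
is numba-compiled; because scipy's special functions cannot be called
from nopython code, the regularized incomplete beta inside the kernel is
evaluated with the standard Lentz continued fraction (everywhere else
scipy is used).

After each sweep past burn-in, the conditional posterior bin means given
the current partition,

    μ̂_i = X̄ + (1 − ŵ)(X̄_block − X̄),   ŵ = E[w | ρ, X] = J(c+2, W)/J(c, W),

are accumulated, along with the change indicators; sweep averages give
the reported posterior means and change probabilities `P_1..P_{n−1}`.
Defaults follow the common practice for this sampler: 50 burn-in sweeps
discarded, 10 000 kept (500 is the classical default; ≥5000 is
recommended because the convergence checker shows that hot-bin posterior
means stabilize to an SD of ≤0.007 across seeds at that length, while
short runs wobble most for low-signal bins). Identical `(config, seed)`
pairs give bit-identical results. The chain starts from the single-block
configuration; chromosome boundaries are deliberately not forced
change-points, since the whole-genome run is what lets a chromosome with
globally elevated density stand out.

Hot-bins are the bins with `μ̂_i` strictly above the same threshold used
by the z-threshold method, and are refined to hot-spots identically.
Correctness of the sampler is checked two ways: against a fully
independent exact-posterior oracle that enumerates all `2^(n−1)`
partitions (with adaptive quadrature for the integrals) on short
signals, agreeing within 3 Monte-Carlo standard errors; and by exact
recovery of planted steps (a 5-bin step of z = 500 on 2000 bins is
recovered with zero false hot-bins).

### Method selection

BCP can miss short signals near the cut-off and behaves erratically on
sparse data, so datasets are routed by two rules: fewer than 300 VIS (but
more than 100) → z-threshold; highly clustered data (`1 − P̄ > 0.98`) →
z-threshold; otherwise BCP. Datasets with ≤ 100 VIS are refused
outright. Automatic switches are logged with the rule that fired, so
summary tables remain auditable.

## Clustering metrics and conservation

`cluster_metrics` reports the maximum-% statistic (sd scale, above) and
the BCP cluster score `1 − P̄`, with flags at 8 and 0.98. Conservation
between two datasets is tested on hot-bins rather than hot-spots to
control for hot-spot size: the 2×2 table (both hot / A only / B only /
neither) over the shared partition's `n` bins is tested with a two-sided
Fisher exact test, defined as the sum of hypergeometric point
probabilities not exceeding the observed table's — the convention under
which the reference worked examples reproduce to their displayed
precision (6.6×10⁻⁵; 0.007; values below 2.2×10⁻¹⁶ are display-floored
by some environments and compared as `p ≤ 2.2e−16`). `conservation_report`
produces the full pairwise matrix; 0.007 is offered as a conservative
significance benchmark for studies whose reference data yield no
hot-spots. No multiplicity correction is applied across the matrix.

## Feature analysis

A feature lies "in" a region when it overlaps by ≥1 bp, counted once per
region. Hot-spot feature densities (features/Mb) are compared to the
genome-wide per-1 Mb-bin density distribution — the full bin vector, not
just its median, because a rank test needs a second sample; the vector's
median is the reported "genome median" — with a continuity-corrected
Wilcoxon rank-sum test, flagged at the Bonferroni level 0.0025
(20 tests: 5 dataset comparisons × 4 feature classes in the reference
design). All bins enter the genome distribution, not only VIS-bearing
ones. The cancer-gene percentage divides cancer-related genes in
hot-spots by all genes in hot-spots (controlling for gene density), with
a Fisher exact enrichment test against the genome-wide catalogue; the
test choice is recorded in output metadata since the reference analysis
reports only non-significance without naming one. Annotation tracks are
user-supplied BED-like files; nothing is downloaded.

## Synthetic data and the size-invariance study

`generate_synthetic_vis` draws a uniform background over the concatenated
genome (chromosomes weighted by length) plus planted clusters, each
uniform over its interval, with per-record truth labels retained. The
default fixtures emulate the two human study conditions the detectors
were designed around: an ALD-like repopulating sample (2401 VIS, five
clusters of 35/61/16/17/20 VIS — 6.2% of the dataset — at the published
hot-spot locations on chr6/11/12/17/17) and an acute-infection-like
reference (922 VIS, three weak clusters of 12/7/8 VIS) used for threshold
calibration.

What the generator does *not* emulate: chromosome- and megabase-scale
density variation of real integration data (real acute data have broad
non-uniformities that produce many weak change points, giving
`1 − P̄ ≈ 0.936` on real repopulating samples versus ≈0.995 on the
uniform-background fixtures — so the highly-clustered fallback rule
should not be exercised on synthetic data), kb-scale dense cores inside
hot-spots, and vector-specific sequence preferences (TSS bias,
palindromic motifs). Passing tests on these fixtures therefore
demonstrate correctness of the algorithms under controlled conditions,
not biological fidelity.

The size-invariance study subsamples a source dataset without
replacement at sizes 200–2000 (10 replicates per size, 120 datasets),
runs each detector with a fixed reference-calibrated threshold, and
Spearman-tests the per-size median of "% VIS in hot-spots" against size.
One master seed spawns an independent stream per (size, replicate). By
default BCP cells below its 300-VIS applicability bound are marked
inapplicable; `apply_selection_rules=False` runs every method at every
size — the design under which the four methods' trends are compared,
since dropping the noisy smallest size only from one method would bias
its trend test. On the synthetic fixture the CIS percentage rises
strongly and significantly with size (ρ ≈ 0.98) while z-threshold and
BCP show no significant trend, reproducing the qualitative contrast the
detectors were built for. Two caveats on that contrast: the absence of a
*significant* trend for the threshold methods is a typical-realization
property, not a sure one — the calibrated threshold lands between the
reference's weakest planted cluster and its strongest background bin, so
across generator seeds it ranges widely (roughly 300–450 on the hg18
fixture), and extreme calibrations can tip the trend test either way
(a low threshold admits noisy small-sample bins, a high one delays
weak-cluster detection). The robust, always-observed form of the result
is comparative: over 50–100% subsamples the novel detectors' median
%-in-hot-spots moves far less than the CIS baseline's. Real hot-spots
additionally contain dense kb-scale cores that keep their bins
detectable at small sizes, which the uniform clusters do not emulate. BCP inside the study uses 500-iteration runs
(the classical default): the study needs many fits, and trend medians
are insensitive to the residual Monte-Carlo noise at that length.

## Shifted partitions and merging

Hot-spot calls can depend on bin placement, so detection can be run on
several shifted partitions (`shiftBins`) and merged: intervals
overlapping by ≥1 bp union into one hot-spot (the criterion is
configurable; no minimum reciprocal overlap is required), statistics are
recomputed from the dataset's VIS inside the union rather than averaged
from the parents, and provenance records the contributing shifts.
Merging is commutative, associative and idempotent. `match_hotspots`
counts ≥1 bp-overlap correspondences between two hot-spot sets and
reports the correspondence ratio relative to the first set.

## Visualization

Three plot styles: genome-wide stripchart (all datasets), per-chromosome
stripchart, and per-bin barplot whose y-axis is the bin rate (never
negative, unlike z). Hot-spot VIS are colored by the quantile class of
their bin's z-score within the dataset's occupied-bin (≥1 VIS) z-score
distribution — ≤85th percentile light blue, (85, 95] dark blue,
(95, 97.5] purple, (97.5, 99] pink, >99 red, ties to the lower class —
and non-hot-spot VIS are grey. The convention (occupied bins, linear
quantiles) is recorded in the run metadata.

## Problem sizes used in the checked examples

The bundled checks run entirely from generated data: the exact-posterior
cross-check enumerates partitions of 8–12-bin signals (the enumeration
oracle is exponential in `n`; the Gibbs sampler itself is routinely run
on the full 3091-bin genome), planted-step recovery uses 2000 bins with
10 000 sweeps, and the size-invariance study runs 12 sizes × 10
replicates × 3 methods on the hg18 partition with 500-iteration BCP
fits. The pipeline and CLI checks use two-chromosome toy genomes of
60–100 Mb.

## Known limitations

- The acute-infection fixtures are synthetic stand-ins; published
  patient-data summaries (e.g. exact hot-spot counts per study) can only
  be recomputed from the original supplementary VIS files placed under
  `data/external/`.
- The Gibbs sampler's within-chain draws are generated by numba's
  per-function RNG; bit-identical reproducibility is guaranteed for a
  fixed numba version.
- Rhesus macaque genome support is not included; any chromosome-sizes
  table can be supplied, but the embedded fixture is human hg18.
- `pct_density` is infinite for zero-width (single-position) hot-spots,
  which can arise from duplicate-position CIS calls.
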