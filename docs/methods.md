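# Methods

This note documents the models implemented in `arcc`, the reasoning behind
the tunable parameters, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Read-pair classification (`arcc.pairs`)

A pair survives quality filtering when both ends have mapping quality ≥ 30
and ≤ 2 mismatches, map to a known chromosome, and neither 5′ base falls in
a blacklisted interval. Surviving pairs are *valid*; valid pairs on
different chromosomes are *trans-informative*; same-chromosome pairs more
than 600 bp apart (strictly greater) are *cis-informative*; the rest are
*valid-noninformative*. Coordinates are 0-based half-open; a pair's
position is the 5′ mapped base of each end and pair distance is
`|pos1 − pos2|`.

The 600-bp threshold reflects the orientation diagnostic implemented in
`orientation_profile`: after ordering ends by coordinate, unligated
fragments are almost exclusively forward–reverse, while true ligation
junctions show all four configurations at ~25% each; the FR excess decays
to noise above roughly 600 bp. Blacklist overlap uses the single 5′ base
because the full alignment extent is not retained in the pairs table; this
is the strictest deterministic rule available from the stored fields.

Duplicates are keyed on both ends' (chrom, pos, strand) after sorting the
two ends by (chrom, pos), mirroring standard duplicate-marking semantics;
the first occurrence in input order is retained.

## Genome binnings (`arcc.binning`)

Fixed-width binning tiles each chromosome left-to-right, retaining the
final partial bin. The RE-anchored ~500-bp segmentation avoids splitting
regulatory elements across bin boundaries: elements within 100 bp are
merged, each merged element grows symmetrically toward 500 bp, and growth
stops where it would touch a neighboring element or chromosome edge.
Growth is implemented as simultaneous unit steps (1 bp right, then 1 bp
left, per round), so closely spaced elements share the gap between them at
equal rates; a single contested base goes to the upstream element and odd
leftover width ends up on the right. Residual gaps are tiled with 500-bp
bins from the gap's left edge, a final short bin absorbing the remainder.
Every input element ends up contained in exactly one regulatory-flagged
bin.

## Contact matrices and normalization (`arcc.matrix`)

Counts are stored per chromosome as upper-triangular sparse matrices over a
binning; same-bin pairs sit on the diagonal but are excluded from decay
fitting and interaction calling (the diagonal is dominated by non-ligation
signal). The distance between two (possibly variable-width) bins is the
distance between their midpoints.

**Balancing.** Knight–Ruiz balancing (inner–outer Newton iteration on
mat-vec products) finds positive weights `x` with `diag(x)·A·diag(x)` having
unit row sums; bins without off-diagonal contacts are masked. Default
tolerance 1e-8 on the row-sum residual; non-convergence raises with
iteration diagnostics. The test suite cross-checks the weights against an
independent Sinkhorn/IPF iteration.

**Distance decay.** `F(d)` is the mean per-pair contact frequency at
distance `d`, estimated per chromosome over 80 log-spaced strata between
`d_min` and `d_max` — zero-count bin pairs are counted in the stratum
denominators — and smoothed by a cubic smoothing spline in log–log space
(scipy's `UnivariateSpline` with its default smoothing factor and weights
proportional to the square root of the stratum read count, the Poisson
scaling of the log-mean's precision). The fit runs twice: bin pairs
significant under the pass-1 model at FDR 0.05 are removed before the
refit, so loops do not inflate the background.

When a visibility model is supplied (the calling path), stratum means are
computed on visibility-corrected counts `n_ij/(v_i·v_j)` over retained
intervals only. This calibration matters: the visibility factors are
median-normalized, so their pairwise products do not average to one, and
fitting `F(d)` on raw counts leaves the binomial expectation
`f = v_i·v_j·F(d)` systematically miscalibrated (measured as an inflated
false-discovery proportion). Fitting on corrected counts restores
`E[n] ≈ N·f` by construction.

**Map normalization.** For aggregate analyses, balanced matrices are
divided by the expected value `N·F(d)` per cell, giving stratum means ≈ 1;
cells outside the fitted range (including the diagonal) are masked, and the
masked range is recorded on the matrix so that downstream rescaling can
exclude those cells rather than average zeros.

**Insulation.** The per-bin insulation score is the mean signal in the
`w × w` square crossing the diagonal at the bin's left edge, log2-scaled
relative to the chromosome mean; the window size is a required parameter
(there is no canonical value) and bins whose window leaves the chromosome
are masked.

**Correction exponent.** `estimate_correction_exponent` returns the grid
exponent `a` maximizing the Pearson correlation between the balancing
weights and reciprocal coverage^a. On pure multiplicative-bias data the
answer is 1.0; on real ARC-C data the shipped calling default is 0.87,
reflecting that reciprocal coverage overcorrects and reciprocal square-root
coverage undercorrects.

## Interaction calling (`arcc.calling`)

The null model is `n_ij ~ Binomial(N, v_i·v_j·F(d_ij))` per chromosome,
tested one-sided (enrichment only) for every retained interval pair with
1 kb ≤ d ≤ 1 Mb. Benjamini–Hochberg correction runs per chromosome over
*all* tested pairs — zero-count pairs contribute p = 1 and enter the
correction denominator analytically. A call passes at q < 0.05 with
strictly more than 5 supporting read pairs. Expected frequencies are
clipped into (1e-15, 1−1e-15); values ≥ 1 are capped with a warning.

Visibility: peaks are intervals at or above the 0.90 coverage quantile of
their chromosome, intervals at or below the 0.10 quantile are removed, and
off-peak coverage excludes contacts whose partner is a peak. Coverage
quantiles, the off-peak median and `N` are all per-chromosome, keeping the
model self-consistent; a flag-level switch to genome-wide pooling was
considered and rejected as inconsistent with the per-chromosome `N`.

Binomial tail probabilities are computed by direct tail summation with a
multiplicative term recurrence; the leading binomial coefficient is
accumulated as a product of small ratios, avoiding the lgamma cancellation
that limits incomplete-beta implementations to ~1e-11 relative accuracy at
N in the millions. Elements whose tail would need more than 4000 terms
(p ≈ 1 territory) fall back to scipy.

## Aggregate contact analysis (`arcc.aggregation`)

For a site set, up to 50,000 same-chromosome site pairs with midpoint
distance in 20 kb – 1 Mb are sampled without replacement (all eligible
pairs when fewer); the "regulated-target" mode instead keeps every eligible
pair with at least one end in a designated subset. 21×21-bin windows of the
normalized map centered on each pair are averaged; the statistic is
log2(center / mean of the other 440 cells), which is invariant under global
scaling of the map.

The permutation null draws 1000 random site-pair sets from a site universe,
each matched to the observed set pair-by-pair on distance stratum (20
log-spaced bins over the distance range) and on both ends' accessibility
strata (deciles of the universe score; default score is the raw cis
coverage of the site's bin). Strata without candidates widen first to the
distance stratum alone, then to the nearest populated distance stratum
(logged). The p-value uses the finite-sample-valid +1 correction,
`p = (1 + #{null ≥ observed}) / (n_sets + 1)`, and q-values are BH across
factors. HOT filtering removes the top 20% of merged peak intervals ranked
by the number of factors calling them (ties broken by genomic order) from
every set, then drops sets left with fewer than 300 peaks.

Differential ACA between genotypes regresses mutant statistics on wild-type
statistics across factors (least squares), removing genome-wide
accessibility shifts; per-factor residuals are tested two-sided against
10,000 draws from the empirical residual distribution.

## Domain aggregation (`arcc.domains`)

Typed domains ("active" / "H3K27me3") of at least 5 kb are extracted with
up to 25 kb of each adjacent opposite-type domain (truncated to the
neighbor's actual extent, absent at chromosome ends), rescaled to a 19×19
grid — domain → central 9×9, each flank → 5 bins — and averaged. Rescaling
is area-weighted averaging (each target cell averages source cells by bp
overlap), which conserves the mean of the source signal; cells masked by
decay normalization (the diagonal band) are excluded from the averages
rather than counted as zeros. TAD strength is the log2 ratio (and percent
difference) of the central square over the four flanking 5×10 side
rectangles, with a two-sided one-sample t-test across per-domain ratios.
Compartment strength applies the same scaling to off-diagonal rectangles of
domain pairs 50 kb – 2 Mb apart and reports the percent difference between
same-type and cross-type central signal. The X chromosome is excluded by
default (no domain annotation there).

The 5×10 side rectangles span the 9 domain rows/columns plus one adjacent
cell on the near-diagonal side. The alternative — extending across the
domain to the opposite flank — would place flank-to-flank cells in the side
blocks, whose compartment-level signal contaminates the side estimate
(measured on simulations as a ~3-point downward bias of recovered TAD
strength).

Two estimator properties are worth knowing. First, decay normalization
partially absorbs domain enrichment: at distances well below the typical
domain size, most pairs are intra-domain, so `F(d)` itself rises toward the
enriched level and the normalized within-domain signal is attenuated. The
attenuation shrinks as domains grow relative to the flank (25 kb) and bin
(5 kb) scales; with the generator's 100–300 kb domains a planted 20%
enrichment is recovered as ~16%. Second, the near-diagonal column of each
side block lies inside the flanking domain, so when flanking domains carry
their own enrichment the side mean is slightly inflated (exactly
(9 + e)/10 on clean planted data).

## Expression correlation (`arcc.expression`)

Pearson correlations of expression across cell types are computed for
gene pairs linked by promoter–promoter interactions; for links with
several candidate gene pairs (bidirectional promoters) the maximum-r pair
is kept. The CV (sd/mean across cell types, sample sd) stratifies genes:
the bottom 30% of the genome-wide CV distribution is "wide expression",
the complementary 70% "regulated expression"; pair subsets require both
genes on the same side of the rank-based cut (ties broken by gene order).
Controls resample the same number of pairs from the linked gene set,
matched per observed pair's distance stratum (deciles of the observed
distance between gene 5′ ends); observed-vs-control mean r is compared by
a two-sided Welch t-test. Gene marking by a chromatin signal uses a strict
`signal > 1.5 × median` rule, so a uniform signal marks nothing.

## The simulator (`arcc.simulate`)

Pair generation factorizes exactly like the calling model:
`P(i,j) ∝ b_i·b_j·F(|m_i−m_j|)·boost(i,j)`, sampled per chromosome by a
multinomial over bin-offset (distance) classes followed by a weighted draw
of the left endpoint within each class, so parameter recovery is
well-posed. The components:

* **Accessibility bias** `b`: regulatory elements are placed with
  exponential gaps to cover ~21% of the genome (widths 150–800 bp); bins
  are biased by RE coverage times an accessibility fold of 4.3, calibrated
  once so that ~21% of the genome captures ~44% of simulated read ends,
  the regime reported for real ARC-C libraries. Optional lognormal
  noise (σ on the log scale) models residual per-bin visibility variation.
* **Distance decay**: power law `d^(−γ)`, γ = 1 by default, the typical
  cis-decay slope in this range; alternatives are a flat law (no distance
  structure, for exponent-estimation checks) and a uniform-distance law
  (for orientation calibration).
* **Planted loops**: bin pairs boosted by a configurable fold, distances
  log-uniform in 2–100 kb by default — the short-range regime where
  regulatory-element interactions concentrate and where a depth-limited
  library has calling power.
* **Domains**: alternating typed domains with no gaps, sizes uniform in
  100–300 kb (several times the 25-kb flank scale, see above), within-domain
  enrichment `e` and same-type preference `r` applied multiplicatively.
* **Read-level nuisance**: independent uniform strands for ligation pairs,
  an optional short (50–500 bp) forward–reverse unligated component, trans
  pairs, and PCR duplicates appended at a configured rate.

Everything is deterministic given the seed, and the generator returns the
ground truth (bias, loops, domain labels, duplicate count) alongside the
pairs.

What the simulator does *not* emulate: polymer-physics contact statistics
(no loop extrusion, no TAD-boundary insulation gradients), sequence-level
reads (no FASTQ, no mapping errors — mapq/NM columns are constant unless
perturbed), chromosome-specific biology (no X-chromosome special casing),
restriction-fragment structure, or inter-replicate variation. Passing
recovery tests therefore demonstrates the pipeline's statistical
correctness under its own model class, not robustness to every artifact of
real libraries.

## Reference study conditions (`arcc.benchmarks`)

The benchmark functions fix the simulation conditions the package is
validated under; sizes are chosen to give tight Monte-Carlo error within
minutes on one CPU:

* orientation calibration: 1 Mb chromosome, 100,000 pairs, distances
  uniform in 601 bp – 100 kb;
* FDR benchmark: one 5-Mb chromosome, 500-bp bins, 2M pairs, γ = 1,
  lognormal bias σ = 0.5, 200 planted 8-fold interactions, 10 replicate
  seeds;
* decay recovery: 5 Mb, 1M pairs, γ = 1, RE bias on;
* domain recovery: two 5-Mb chromosomes, 2M pairs, e = 1.2, r = 1.5,
  analyzed at 5-kb bins;
* loop ACA: 5 Mb at 1-kb bins, 3M pairs, 300 planted 3-fold loops at
  25–250 kb (sized so the ACA statistic's sampling error is well inside
  ±0.15);
* exponent estimation: 2 Mb, 1M pairs, flat distance law, σ = 0.5;
* permutation calibration: 2,000-site universe, 200 null factors of 40
  sites each, 1000 matched null sets per factor.

## Known limitations

* The fixed 0.87 visibility exponent assumes moderately dispersed,
  unimodal coverage bias. Under strongly bimodal bias (e.g. a pure
  RE-fold bias with true exponent 1.0), the under-correction of
  high-coverage intervals concentrates false calls there and measured FDP
  can exceed the nominal level several-fold; re-estimating the exponent on
  the dataset (`estimate_correction_exponent`) is advisable when coverage
  is strongly structured.
* TAD-strength recovery is attenuated by background absorption (above);
  compare strengths between conditions rather than reading them as
  absolute enrichment factors.
* Calling is cis-only; trans-informative pairs are classified but not
  tested.
* The two-pass decay refit removes point outliers but not broad structural
  enrichment (domains), which therefore remains part of the background.
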