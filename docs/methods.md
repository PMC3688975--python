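# Methods

## Data model and assumptions

A cohort is a probe matrix: probes with genomic coordinates (0-based,
half-open throughout the library; BED/bedGraph output keeps that convention,
human-readable reports are 1-based inclusive) and one log2-ratio column per
sample. The generative assumption behind every stage is piecewise-constant
copy number per sample plus i.i.d. Gaussian probe noise; replicate probes
are merged to their per-sample median before analysis, and missing ratio
cells are excluded probe-wise per sample.

## Centering

Population-level normalization of aCGH ratios is upstream of this package;
what remains per sample is fixing the copy-neutral baseline. `center_profile`
subtracts the argmax of a Gaussian KDE of the ratio distribution (512-point
grid over the data range; median fallback for degenerate input). Mode
centering tracks the copy-neutral bulk rather than the mean, so amplified
regions do not drag the baseline — provided aberrant probes remain a
minority. That assumption holds on genome-wide arrays; it fails by
construction if more than half the probed genome is aberrant, which is why
the synthetic defaults keep planted amplicons well under half of the probed
span.

## Circular binary segmentation

`cbs_segment` implements recursive CBS. Within a stretch of `n` probes the
arc `(i, j]` of length `k` is scored by the two-sample contrast

    Z(i, j) = |S_ij − k·T/n| · sqrt(n / (k (n − k)))

where `S_ij` is the arc sum and `T` the stretch total. The usual pooled
noise scale is omitted: it is identical for every arc and invariant under
permutation of the stretch, so it cancels from the permutation comparison.
Complementary (wrap-around) arcs give the same |Z| and the same boundary
pair, so a linear scan over `i < j` covers the circular statistic.

Only arcs whose induced pieces all have ≥ `min_probes` probes are
admissible (this is how the minimum-segment rule is enforced; no separate
pruning pass). Ties are broken toward the smallest left index, then the
smallest arc length.

The split decision uses the permutation p-value `p = (b + 1)/(B + 1)` over
random shuffles of the tested stretch (the +1 correction avoids p = 0),
accepted when `p < α`. Defaults: α = 0.01, B = 10 000, `min_probes` = 5.
Permutations run vectorized in geometrically growing batches with
sequential early stopping in both directions:

* **stop-reject** as soon as the exceedance count `b` guarantees
  `p ≥ α` — exact, no approximation;
* **stop-accept** when the Clopper–Pearson upper 99.9% bound on the
  exceedance probability falls below α (at least 100 permutations always
  run). This trades a ≤ 0.1%-confidence approximation on clearly
  significant splits for an order-of-magnitude speedup; marginal splits
  near α still run the full B.

No "undo" pruning of adjacent segments is applied afterwards; segment means
are recomputed as exact means of member probes, and segment spans tile the
probe-covered span (boundary = first probe of the right-hand segment).

## Sample-adaptive threshold

`estimate_sat` estimates per-sample noise as the normal-consistent MAD of
first differences of consecutive probe ratios divided by √2 — differencing
cancels the piecewise-constant signal while doubling the noise variance, so
the estimator is robust to the very aberrations being called. The threshold
is `τ_s = max(floor, k · noise)` with floor 0.15 and k = 3 (both
config-exposed). With the default generator noise of σ = 0.065 log2 units
this yields a median τ near 0.20, matching the scale reported for tumor
aCGH cohorts: quiet arrays sit at the floor, noisy hybridizations scale up.

## Calling, frequency and amplitude

Gain/loss comparisons are strict (`v > τ`, `v < −τ`): a segment mean exactly
at the threshold is neutral. Gain frequency divides by the full cohort size
(a config flag allows region-restricted denominators); conditional amplitude
averages the segmentation line over gained samples only and is reported as
missing where no sample is gained. Gene copy number is the overlap-length-
weighted mean of segment means across the gene span.

## Breakpoints and hotspot testing

A segment boundary is a breakpoint iff the shift exceeds τ_s, or both
flanking means lie above +τ_s (shifts within amplified regions; a
config-switchable `abs` mode also admits loss contexts). The event position
is the end of the left segment.

Windows are anchored at multiples of the window size (default 50 kb), not at
region edges, so the grid is reproducible regardless of the region queried;
a region selects the windows it overlaps. Eligibility requires ≥ 1
overlapping probe (array coverage) and zero overlap with any CNV interval
(any-overlap rule — germline variants would confound somatic breakpoints).
Binning conserves counts: binned + dropped (ineligible/off-grid) equals
total called breakpoints.

The enrichment null re-places the region's total observed breakpoints
uniformly at random among its eligible windows (one multinomial draw per
permutation); per-window `p = (#{count ≥ observed} + 1)/(B + 1)`, floor
1/(B+1). Placement is uniform per window, pooled across samples; a
probe-density-weighted or per-sample-stratified null is deliberately out of
scope of the default (uniformity is the interpretable reference null, and
eligibility already removes uncovered windows). Being Monte-Carlo estimates
of discrete tail probabilities, these p-values are slightly conservative
(super-uniform) — the calibration tests therefore check the empirical CDF
against the KS band per replicate and validity `P(p ≤ α) ≤ α + slack`,
rather than expecting literal continuous uniformity of pooled p-values.

## Sequence elements

The quadruplex scanner matches `G{3}(N{1,7}G{3}){3}` with lazy loops,
non-overlapping, left to right, resuming after each match end — the
reference "minimal match" behavior; an `overlapping=True` mode reports every
start position with a minimal match for sensitivity analysis. `N` never
matches. Both strands are scanned by default (the complementary C-pattern,
kept even when it overlaps a G-hit: distinct strands). Motif length is
bounded by the pattern: 15–45 bp.

Window element content uses interval unions clipped to the window
(double-covered bases count once) — irrelevant for real RepeatMasker tracks,
which rarely self-overlap within a class, but well-defined on synthetic
data. G4 content is union base pairs of motif sequence per window.

## Association statistics

Median splits are strict: "above" means content > median; ties go below
(config-switchable). Degenerate (all-equal) splits are flagged rather than
tested. The fold ratio divides mean breakpoints per above-median window by
the below-median mean (infinite fold flagged when the denominator is zero);
the accompanying test is the package's Mann-Whitney.

Fisher's exact test is two-sided by the probability-mass rule (sum of
hypergeometric masses ≤ the observed table's), via `scipy.stats.fisher_exact`,
verified exactly against a full enumeration oracle on all small-margin
tables. Region-vs-region enrichment counts above/below-median windows per
region with the median taken from a configurable scope (genome scope by
default); a column that is empty on both sides (all windows on one side of
the median) is reported as no association (p = 1, OR = 1).

Mann-Whitney uses midranks; U is reported for the first sample. The p-value
is exact — full enumeration of group assignments of the pooled midranks —
when min(n, m) ≤ 8 and the enumeration stays small, otherwise the
tie-corrected normal approximation. Spearman is midrank-based with exact
enumeration p for n ≤ 9 and the t-approximation above. Benjamini–Hochberg
q-values come from `statsmodels` (step-up with monotonicity enforcement).

## Synthetic data

The generator emulates the statistical structure of a zoom-in aCGH study of
a tumor cohort:

* **Cohort**: 68 arrays by default, 58 of them with matched expression,
  plus 154 expression-only samples (expression cohort of 212) — membership
  and true segments are generated for all, probe matrices only for arrays.
* **Profiles**: per-sample Bernoulli inclusion per amplicon (independent
  across samples unless a membership matrix is supplied — the simplest null
  for co-occurrence analysis), piecewise-constant means, Gaussian probe
  noise σ = 0.065 (chosen so the SAT median lands near 0.20), probe spacing
  10 kb.
* **Hotspots**: amplicon edges may be drawn uniformly from a configured
  window per sample, which concentrates true breakpoints there.
* **Sequence**: random A/C/G/T (optionally G-free A/C/T, which makes
  planted motif counts exact — no chance motifs); G4 motifs planted at
  recorded non-colliding positions, bounded retries then error.
* **Elements**: per class, an alternating gap/length renewal process with
  exponential lengths calibrated so expected coverage equals the configured
  density (defaults 19.2% LINE, 10.8% SINE, 7.5% LTR — typical genome-wide
  window medians); intervals never overlap within a class.
* **Expression**: `slope × true gene copy + N(0, noise)`, slope 1 and noise
  0.5 by default — monotone in copy number at zero noise.
* **Scaled coordinates**: the default study uses two chromosomes of 6.4 and
  12.8 Mb carrying a 6p22-like amplicon (with a target/intervening/auxiliary
  gene trio supporting exclusion events) and three 1q21-24-like amplicons.
  Amplicons stay a minority of the probed span so mode centering is valid.

What the generator does **not** emulate: array image artifacts, dye bias,
GC waves, probe-specific affinity, clonal heterogeneity mixtures, or ploidy
shifts. Passing tests therefore demonstrate correctness of the algorithms
under the stated noise model, not robustness to those real-data artifacts
(the centering and SAT stages are the ones that would absorb them first).

## Numerical choices and degenerate inputs

* Random streams: a single seed; the generator derives named child streams
  (CRC-keyed `SeedSequence` spawn keys), so outputs are reproducible and
  independent of call order; cohort segmentation spawns one child per
  sample.
* Exactness claims on noise-free data hold for dyadic amplitudes (e.g. 1.0),
  where floating-point means are exact.
* Detected boundary positions live on the probe grid; classifying a
  boundary into a sub-probe-spacing feature (e.g. a 2-kb promoter) requires
  spacing at or below that feature's size.
* Promoter span: 2 kb upstream of the transcription start on the annotated
  strand (config-exposed).
* Degenerate cases: constant profiles center to zero and yield one segment;
  all-equal median splits are flagged; empty amplified groups are skipped in
  group tests; constant vectors give undefined (flagged) correlations;
  chromosomes shorter than the minimum probe count become single segments.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` run the full method on scaled
problems chosen as this package's own validation sizes: chromosomes up to
12.8 Mb at 10-kb spacing (≈ 1 300 probes), cohorts of 10–24 samples, CBS
with B = 300–1000 permutations and breakpoint nulls with B = 1000. The
library defaults remain the full-scale settings (B = 10 000, α = 0.01,
5-probe minimum); the sequential early stopping described above is what
makes those defaults usable on cohort-scale data.

## Known limitations

* No undo/pruning step after CBS: very long, low-noise chromosomes
  accumulate the per-test α across recursion levels, so occasional spurious
  micro-segments appear at rates consistent with α per tested stretch.
* The SAT is this package's operational definition (difference-MAD with
  floor and multiplier); it reproduces the reported floor/median scale but
  is not derived from an external normalization pipeline.
* Breakpoint positions are probe-grid-limited; no sub-probe refinement.
* Absolute copy number, ploidy/purity correction and allele-specific
  analysis are out of scope.
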