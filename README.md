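# focalamp

Analysis of **focal genomic amplifications in array-CGH cohorts**: segmentation
of probe-level log2 ratios, sample-adaptive gain/loss calling, amplification
frequency and amplitude maps, breakpoint hotspot permutation testing,
repeat-element and G-quadruplex window statistics, copy-number/expression
integration, and amplicon architecture analysis (co-occurrence patterns and
gene-exclusion events).

The package targets cancer-genomics analysts working with tumor-vs-reference
oligonucleotide aCGH data — the setting where recurrent focal amplifications
(e.g. at 6p22 or 1q21–24 in urothelial carcinoma) must be fine-mapped, their
boundaries tested for clustering, and their candidate driver genes ranked by
copy-number–expression coupling. A first-class synthetic-data module generates
cohorts with known planted truth, so every stage is testable end to end
without external downloads.

## The model

Each sample's probe log2 ratios `r_i = log2(tumor/reference)` are modeled as a
piecewise-constant copy-number profile plus i.i.d. Gaussian noise. The
pipeline stages are:

1. **Centering** — the profile is shifted so its modal (copy-neutral) level
   is zero, using the argmax of a kernel density estimate of the ratio
   distribution (robust to large amplified fractions, unlike mean centering).
2. **Segmentation** — circular binary segmentation (CBS): recursively find
   the arc `(i, j]` maximizing the contrast statistic

   `Z(i,j) = |S_ij − k·T/n| · sqrt(n / (k(n−k)))`

   (`S_ij` arc sum, `k` arc length, `T` total) and accept the split when its
   permutation p-value `(b+1)/(B+1)` falls below α. Defaults follow common
   practice for aCGH: α = 0.01, B = 10 000 permutations, minimum 5 probes per
   segment.
3. **Sample-adaptive threshold (SAT)** — a per-sample gain/loss cutoff
   `τ_s = max(0.15, 3 · MAD(Δr)/√2)` where `MAD(Δr)` is the
   normal-consistent MAD of first differences of consecutive probe ratios:
   noisier arrays require larger segment means before a call.
4. **Calling** — probe `i` is a *gain* in sample `s` iff the segmentation
   line exceeds `+τ_s` (strictly), a *loss* below `−τ_s`. Gain frequency
   `f_i` = gained samples / cohort size; conditional amplitude `a_i` = mean
   segmentation value over gained samples only.
5. **Breakpoints** — a boundary between adjacent segments is a breakpoint
   iff `|m_right − m_left| > τ_s`, or both means lie above `+τ_s` (a shift
   inside an amplified region). Pooled breakpoints are binned in
   genome-anchored 50-kb windows (array-covered, CNV-free windows only), and
   per-window clustering is tested against `B` uniform re-placements of the
   observed breakpoints: `p = (#{perm count ≥ observed} + 1)/(B + 1)`.
6. **Sequence elements** — G4 quadruplex motifs are minimal, non-overlapping
   matches of `G{3}N{1,7}G{3}N{1,7}G{3}N{1,7}G{3}` (and the complementary
   C-pattern); LINE/SINE/LTR content is the union-covered fraction per
   window. Above- vs below-median windows are compared by breakpoint-rate
   fold ratios (rank-sum test) and between regions by two-sided Fisher exact
   tests.
7. **Expression integration** — gene copy number (length-weighted mean
   segmentation value over the gene span) is correlated with expression by
   midrank Spearman ρ (exact p for n ≤ 9), FDR-controlled with
   Benjamini–Hochberg; amplified-vs-rest expression shifts are tested by
   Mann-Whitney (exact for small groups, tie-corrected normal otherwise).
8. **Amplicon architecture** — region-level amplicon calls (≥ 25% of the
   span gained by default), co-occurrence pattern counts with exclusion-rule
   checking, and detection of *gene-exclusion events*: amplifications that
   fully include an auxiliary gene while excluding the canonical target,
   with the proximal boundary interrupting an intervening gene's coding or
   promoter region.

## Worked example

`examples/01_segment_and_call.py` simulates a 6-sample cohort with one
planted 1.2-log2 amplicon (probe noise σ = 0.065) and segments it:

```
sample S004: SAT = 0.214 (noise estimate 0.071 log2 units)
chrom   start     end  n_probes     mean
chr6s       0 1200000       120 0.000062
chr6s 1200000 2400000       120 1.197088
chr6s 2400000 3990060       160 0.001624
truth: amplicon present = True

peak gain frequency 0.17 at chr6s:1,200,000 (mean amplitude when gained 1.20 log2)
```

The segment table recovers the planted amplicon span (1.2–2.4 Mb) and
amplitude (1.2); the SAT of 0.214 reflects this array's noise (≈ 3 × 0.071).
One of six samples carries the amplification at this locus, hence the peak
frequency 0.17, while the conditional amplitude averages only over amplified
samples and stays at 1.20.

The other examples demonstrate amplicon co-occurrence and gene-exclusion
detection (`02`), breakpoint hotspot testing (`03`), motif/element window
statistics (`04`) and expression integration (`05`); each prints the numbers
it computes with a line on what they mean. A thin CLI mirrors the stages
(`focalamp simulate|segment|breakpoints|elements|run`).

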