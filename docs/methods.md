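# Methods

## Model and procedure

The pipeline treats a differential ChIP-seq comparison between two
conditions (male and female liver in the motivating setting) as a
per-site two-sample Poisson problem. Read counts in a fixed window are
assumed Poisson-distributed with a condition-specific rate; the question
at each site is whether the two rates differ, and in which direction.

**Counting.** For every peak the summit — the base of maximal
enrichment reported by the upstream peak caller — anchors a 300-bp
window (clipped at position 0 near chromosome starts). Window counts are
taken from per-condition coverage tracks. Tracks built from read 5′
positions ("point-read" tracks) make the window sum an exact read count;
run-length coverage (wiggle/bedGraph) is summed per base. For the Pol2
transcription score the count is taken over the genomic span between a
gene's TSS and TES, strand-agnostically, since read counting does not
depend on gene orientation.

**The two-sample test.** Two variants are implemented, selectable via
`ScoreConfig.test_method`:

- `conditional_binomial` (default): conditional on the total
  n = k_A + k_B, under the null of equal rates k_A ~ Binomial(n, w)
  with w = N_A/(N_A + N_B) for library sizes N_A, N_B. The reported
  p-value is the one-sided exact tail in the direction of the observed
  excess. This is the standard exact comparison of two Poisson rates and
  is well calibrated: under the null the chance of clearing the High
  threshold (p < 10^−6.4) is about 2·10^−7 per site, so a 10⁵-site null
  landscape is expected to produce ≲ 0.1 false High calls.
- `poisson_tail`: the larger count (after normalization) is evaluated as
  an upper tail P(X ≥ k_max) of a Poisson whose rate is the smaller
  count rescaled to the larger side's library (λ = k_min · N_max/N_min,
  floored at λ_min = 1 so that (k, 0) pairs remain finite). This mirrors
  a historically common shortcut, but conditioning on the smaller
  observed count as if it were the true rate double-counts
  opposite-direction fluctuations and makes the test anticonservative
  (measured ~10⁻³ of equal-rate λ=50 pairs clear the High threshold).
  It is retained as an explicit interpretation, not used by default.

Both variants agree with independent term-by-term tail summations to
better than 10⁻¹² relative error over all count pairs up to 200 (checked
in the test suite and recomputed by `scripts/acceptance.py`).

**The signed score.** p is transformed to
score = ±log2(−10·log10 p), positive when condition A (male) is
stronger. Algebraically |score| > 6 ⟺ p < 10^−6.4 ≈ 4·10⁻⁷ and
|score| ≥ 3 ⟺ p ≤ 10^−0.8 ≈ 0.16. When −10·log10 p ≤ 1 (p ≥ 10^−0.1) the
log2 would be non-positive or undefined; the score is clamped to 0
there, as it is for exact ties (no direction). The clamp only affects
deeply non-significant sites. p-values are floored at `p_floor`
(default 10⁻³⁰⁰), capping |score| at log2(3000) ≈ 11.55.

**Strata and calls.** Scores stratify as High (|s| > 6),
Medium (3 ≤ |s| ≤ 6), Low (|s| < 3); both boundaries belong to Medium,
with High strict per the ">6" significance convention. A gene is
male-dominant iff ≥ 1 assigned peak has score > 6 AND its Pol2 score
is > 6; female-dominant is the mirror with both < −6. Since a single
Pol2 score cannot be simultaneously > 6 and < −6, a gene cannot receive
both calls.

**Interval rules.** Two condition peak sets are partitioned into common
(sharing ≥ 1 bp with any peak of the other set; intervals are half-open,
so bookended peaks do not overlap) and unique peaks, reported per set —
common_a and common_b need not be equal since pairing can be
many-to-one. Feature annotation classifies each summit with precedence
TSS > TES > exon > intron > intergenic, where TSS/TES means within
500 bp of the respective gene end (the TES window mirrors the stated TSS
window; ties between candidate genes break to the smaller gene id).
Gene assignment offers `nearest_tss` (minimum |summit − TSS|, id
tie-break) and `tss_window` (every gene with the summit within 10 kb
up/downstream of its TSS, strand-oriented, boundaries inclusive; the
pipeline default). Observed-vs-expected category tests (chromosomes or
feature classes) use an exact two-sided binomial against expected
N·length/genome_length. PCR duplicates are removed by keeping at most
two reads per (chromosome, 5′ position, strand) key; read length is
deliberately ignored in the key.

**Expression screen and integration.** The expression matrix (linear
intensities, ≥ 2 replicates per condition; duplicate probes collapse to
the probe of maximal mean intensity) is tested with a two-sample Student
t-test on log2 values — the equal-variance form by default, as is
standard for microarray intensities of this vintage, with a Welch option
— while the fold change is the ratio of larger to smaller linear
condition mean. A gene passes at fold change > 1.5 and p < 0.1 (raw; no
multiple-testing correction is applied, matching the screening intent of
the thresholds). The final integrated call requires the dominance call
and the expression direction to agree; conflicting directions yield
"none" with all three evidence flags reported.

## Synthetic data: what it emulates, and what it does not

The generator plants known structure so every stage can be verified
end-to-end:

- genome: 2 chromosomes × 5 Mb; 200 genes on a regular grid (4–10 kb
  long, 2–5 exons, alternating strands, ≥ 24 kb margins so neighbouring
  ±10 kb TSS windows stay disjoint from planted peaks);
- peaks: 2,000 total, width 400 bp with mid-interval summits; 80%
  shared between the condition peak sets (mirroring the ~80% common
  fraction typical of such comparisons), the rest called in one
  condition only; null peaks sit on a genome-wide grid kept clear of
  planted intervals;
- planted effects: 10% of genes male-dominant and 10% female-dominant.
  Each dominant gene gets one peak within ±2 kb of its TSS with window
  rates (λ₀·m, λ₀) oriented by class, a Pol2 gene-body rate asymmetry of
  the same factor, and an expression log2 fold change of log2 m. The
  defaults λ₀ = 50 reads per 300-bp window, m = 4, Pol2 baseline 60
  reads per gene body represent a strong, unambiguous biological signal
  — the regime the scoring scheme is designed to flag;
- tracks: point reads, so each window count is an exact Poisson draw;
  a uniform background of 0.001 reads/bp is added to both conditions;
  library-size normalizers are equal by default;
- expression: log2 intensities N(8, 1) baseline, replicate noise
  σ = 0.2 (log2), 3 replicates per condition.

A single seed drives all stages through derived substreams
(`default_rng([stage, seed])`), so outputs are bit-reproducible and
stages can be regenerated independently.

Real data differ in ways the generator deliberately omits: overdispersed
counts (biological replicates, copy-number and mappability artifacts),
fragment-length smearing, GC bias, peak-width and height heterogeneity,
correlated neighbouring sites, and annotation ambiguity. Passing the
recovery tests therefore demonstrates that the scoring and
classification rules are implemented correctly and are well calibrated
under their own Poisson assumptions — not that the thresholds have any
particular sensitivity/specificity on real chromatin.

## Numerical choices and degenerate inputs

- (0, 0) count pairs give p = 1, score 0; zero-coverage genes likewise.
- λ_min = 1 floors the `poisson_tail` rate so (k, 0) pairs stay finite.
- `p_floor` = 10⁻³⁰⁰ avoids p = 0 and infinite scores.
- Ties: equal normalized counts → direction "none" → score 0; equidistant
  TSS ties → smaller gene id; duplicate peak names → ".2", ".3" suffixes.
- Height stratification uses right-open bins plus an overflow bin, so a
  boundary-valued height falls in the upper bin.
- Coordinates are 0-based half-open everywhere; UCSC wiggle (1-based) is
  converted on read. narrowPeak summit offsets of −1 fall back to the
  interval midpoint.
- The signed score clamp (q ≤ 1 → 0) and the score cap from `p_floor`
  are the only departures from the pure formula.

## Problem sizes

The default test and acceptance runs use the generator defaults above
(200 genes / 2,000 peaks / ~1.2 M reads per factor and condition), 10⁵
pairs for null calibration, and all count pairs ≤ 200 for oracle
equivalence; a full run of everything completes in well under a minute.

## Known limitations

- No replicate-aware dispersion modelling: counts are pooled per
  condition, as in the two-sample design the score was built for; with
  biological replicates a negative-binomial framework (e.g. DESeq2-style)
  would be preferable on real data.
- No multiple-testing correction anywhere (by design of the screening
  thresholds); the High threshold is stringent enough that genome-scale
  false positives are rare only under the Poisson null.
- Peak calling is upstream and out of scope; the pipeline consumes
  called peaks and trusts their summits.
- The `poisson_tail` variant is provided for comparability, not
  inference; its calibration caveat is documented above.
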