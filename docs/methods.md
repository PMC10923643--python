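# Methods

## The analysis model

`fruitmethyl` implements the standard windowed WGBS differential-
methylation analysis for a three-stage developmental series (young,
expanding, mature fruit — YF/EF/MF). Bisulfite sequencing converts
unmethylated cytosines to thymine, so a cytosine covered by n reads of
which c read as C has observed methylation c/n. All inference is on these
per-cytosine counts; reads themselves are out of scope (alignment and
per-read extraction happen upstream, in methratio-style tables).

**Contexts.** Each cytosine is classified by the two bases 3′ of it on its
own strand: CG, CHG, CHH (H ∈ {A,T,C}). Minus-strand cytosines (plus-
strand Gs) are re-derived from the reference by complementing the two
upstream plus-strand bases. Symmetric CG/CHG sites are deliberately *not*
merged across strands: each strand's cytosine is an independent record,
matching per-strand extractor output and keeping weighted levels
well defined under pooling.

**Conversion and methylcytosine calls.** The non-conversion rate is the
pooled maximum-likelihood estimate over the unmethylated spike-in
control, p₀ = Σc/Σn; conversion = 1 − p₀. A site is a methylcytosine when
the one-sided exact binomial upper tail P(X ≥ c | n, p₀) falls below α =
0.05 (exposed as a flag). The test is one-sided because the only
alternative of interest is methylation in excess of non-conversion noise.
No multiple-testing correction is applied to site-level calls — that is
the convention this pipeline mirrors; callers that want control at scale
can lower α. Uncovered sites (n = 0) are untestable and counted, never
silently treated as unmethylated.

**Weighted levels.** The level of any site set is Σc/Σn (#C/(#C+#T)).
This makes levels exactly decomposable: the pooled level equals the
count-weighted mean over any partition, a property the tests assert. An
empty or zero-coverage set raises a no-data error rather than returning
0 — 0/0 is not a methylation level.

**DMR calling.** Chromosomes are tiled into fixed 200-bp windows (the
final short window is retained and flagged truncated). Per window and
context, counts of the two samples are pooled and compared by two-sided
Fisher's exact test (two-sidedness by summing all tables with point
probability ≤ the observed table's). BH q-values are computed per context
over all *testable* windows; a window is a DMR iff |Δ| strictly exceeds
the context threshold (CG 0.4, CHG 0.2, CHH 0.1), p < 0.05 and q < 0.05.
Direction is hyper when the later sample is more methylated. Testability
requires ≥ 10 reads and ≥ 3 context cytosines per sample per window —
floors chosen to keep Fisher's test meaningful; both are `DmrParams`
fields. Replicates, where present, are pooled into counts before
windowing. Shared DMRs between two comparisons are coordinate-identical
windows of the same context; concordance is the fraction with equal
direction. Genome DMR coverage divides the union of DMR windows by total
assembly length (control excluded); covered-sequence length is a
defensible alternative denominator not used here.

**Profiles.** Metagene profiles map each feature's 2-kb upstream flank,
proportionally scaled body and 2-kb downstream flank onto 20 + 40 + 20
bins (bin 0 always 5′-most; minus-strand features are reflected), pooling
counts across features — so pooled profiles are exactly count-weighted
combinations of subset profiles, and a uniform methylome is flat to
machine precision. Features shorter than the body bin count are skipped
and counted. DMR density around TSS/TES counts DMR *midpoints* per 100-bp
bin within ±2 kb of each anchor (midpoints avoid double counting across
bins), normalized per feature per kb. The background places an equal
number of length-matched regions uniformly on the genome (control
excluded) per permutation; the enrichment p is the standard add-one
estimate (1 + #{perm ≥ obs})/(1 + N) on the total anchored count. The
randomization scheme is declared, not inferred from any upstream tool.

**Association.** DEGs are thresholded from supplied statistics —
|log₂FC| > 2 and adjusted p < 0.05, strict inequalities, boundary values
non-significant; the expression model itself is fit elsewhere. A DMG is a
gene whose body ± 2 kb intersects ≥ 1 DMR by any base-pair overlap (the
promoter flank is the 2 kb 5′ of the TSS, strand-aware). Enrichment of
DEGs among DMGs is the one-sided upper-tail hypergeometric test with the
universe defaulting to all annotated genes; both the universe and the
flank are parameters.

## The simulator

The generator emulates the statistical structure the analysis assumes,
not sequencing itself (no FASTQ, no error model beyond non-conversion, no
TE families).

* **Genome**: i.i.d. bases at a requested GC fraction (default 0.35, a
  typical citrus-like value) across `n_chromosomes`, plus a separate
  fully unmethylated control contig carried in the same FASTA under a
  reserved name — one-file spike-in practice. Genes (1–3 kb, random
  strand) are packed without overlap; packing infeasibility raises an
  error naming the constraint. TEs are placed uniformly and may overlap
  genes, as real TEs do.
* **Levels**: each cytosine draws one latent quantile u ~ U(0,1), shared
  across stages; its stage level is the Beta quantile at the stage ×
  context mean with concentration κ = 20. Beta(mean, κ) reproduces the
  U-shaped overdispersion of real per-site methylation with two
  parameters. Sharing u makes a site's level positionally stable across
  stages — as in real methylomes — and, crucially, makes windows with
  equal stage means *exactly* null: with independent per-stage draws,
  between-stage biological variance would inflate Fisher false positives
  under the null and the caller could never be calibrated against its own
  FDR level.
* **Defaults** mirror the developmental narrative: CHH means
  0.066 → 0.153 → 0.145 across YF/EF/MF with CG/CHG declining
  (0.60/0.55/0.52 and 0.40/0.36/0.34), coverage Poisson(40) with a floor
  of 1, non-conversion 0.01, and 10% of 200-bp windows given a
  context-specific true shift (CHH +0.15, CHG −0.25, CG −0.45) applied
  identically in EF and MF — so the two later-stage comparisons share
  their differential windows with matching direction, the shared-DMR
  behaviour the analysis measures.
* **Named study conditions.** `SimulationSpec.recovery()` holds stage
  means flat and plants only the +0.15 CHH shift in 10% of windows at
  40× — the condition under which recall/false-discovery calibration is
  meaningful, because the planted windows are then the *only* truly
  differential ones. `SimulationSpec.null()` is flat with no shifts.
  Under the narrative-style default, the genome-wide CHH drift (+0.087
  between YF and EF) makes many unplanted windows genuinely differential,
  so the demo scorecard's "false-discovery proportion" (measured against
  planted windows only) overstates false discovery there by design;
  recall is the meaningful scorecard number for the default demo.
* **Level recovery** is checked with `diff_window_fraction = 0`: with
  shifts planted, the genome-wide mean is mean + fraction × effect by
  construction, a property of the shift mechanism rather than of level
  recovery. Recovered weighted levels include the non-conversion
  inflation (1 − level)·r ≈ +0.009 at r = 0.01 — the pipeline, like the
  extractors it mirrors, does not subtract non-conversion from observed
  ratios; the ±0.01 recovery tolerance accounts for it.
* **Expression**: true DMGs become DEGs (|log₂FC| ≥ 4, adjusted
  p ∈ [1e-8, 1e-3], sign random, drawn once so coupled DEGs are shared
  across comparisons) with coupling probability 0.9 by default; 10% of
  the remaining genes are background DEGs for methylation-unrelated
  reasons — real transcriptomes always contain these, and without them an
  uncoupled study would have no DEGs at all and the enrichment p would
  degenerate to 1. With coupling 0, the enrichment p is uniform over
  seeds (tested by Kolmogorov–Smirnov at 200 seeds).
* **Determinism**: all randomness flows from one integer seed through
  named substreams (genome, genes, TEs, windows, levels, counts,
  expression); identical seed + spec gives byte-identical output files.

## Problem sizes and numerical choices

Validation studies use 300–600-kb genomes (≈ 95k–200k cytosines, 1.5k–3k
windows), large enough that genome-wide level standard errors (≈ 2×10⁻⁴)
and Monte-Carlo slack are far below the tolerances tested, while the full
suite runs in well under a minute per study. Enrichment validation uses a
*sparse* shift plan (1% of windows, CHH only): at desk-scale genome sizes
the default 10%-of-windows plan puts a planted window within ±2 kb of
essentially every gene, DMGs saturate the universe, and the
hypergeometric test is powerless by construction — a structural property
of dense differential methylation, not of the implementation.

Coordinates are 0-based half-open everywhere internally; 1-based only at
file boundaries (methratio TSV, GFF3). N-containing context windows are
dropped, not imputed. BH ties resolve by the standard step-up cumulative
minimum. Fisher two-sidedness follows the point-probability convention;
the tests hold an exact rational-arithmetic enumeration oracle against it
(all margins ≤ 12, tolerance 1e-10) and an exact tail-summation oracle for
the binomial caller (all n ≤ 50, tolerance 1e-12).

## Limitations

Passing tests show the pipeline is correct and calibrated *under the
generative model above*: binomially sampled counts around Beta site
levels with position-independent coverage. Real bisulfite data add
mapping bias, coverage autocorrelation, chromosome-scale methylation
domains (pericentromeric TE seas), batch effects between replicates, and
incomplete-conversion heterogeneity — none of which the simulator
emulates, so calibration on real data must be established separately.
The windowed Fisher approach pools replicates and cannot model biological
dispersion between them (beta-binomial and regression DMR callers exist
for that); the window thresholds are field conventions, not fitted
quantities. Hypergeometric DEG/DMG association is correlational; no
causal claim about methylation driving expression (or organic-acid
metabolism) follows from it.
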