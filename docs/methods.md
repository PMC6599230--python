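# Methods

This note documents the statistical model, the conventions, the synthetic
data generator, and the deliberate design choices of `medipdmr`.

## Coordinates and intervals

All internal coordinates are 0-based, half-open `[start, end)` (the BED
convention). Width is `end − start`; this is the convention under which the
widths printed in the bundled published result tables equal `end − start`
of their printed locations for all 88 rows (a 1-based inclusive reading
would make every width one larger). Location strings accept en-dashes,
hyphens, and digit-group commas; the canonical form is `chrN:start-end`.
Interval merging coalesces book-ended intervals (`end == next start`), so
consensus regions never fragment at abutting peaks; half-open *overlap*, by
contrast, requires at least one shared base, so touching intervals do not
overlap.

## Consensus peaks

An individual's consensus set is built from the merged union of its
technical-replicate peak calls, keeping a merged region iff every replicate
has at least one peak overlapping it (≥ 1 bp; fractional-overlap thresholds
are deliberately not offered, as no principled default exists). The cohort
master set applies the same rule across individuals with a configurable
support threshold, default `min_overlap = 2` — the common default of
consensus peak tools. Retained intervals are the merged union spans, not
intersections, so read counting covers the full enriched region. Counts for
a master peak are summed over all overlapping regions of each replicate
count table and over the replicates of each individual; missing regions
count as zero.

## The differential test

The count model is the standard gamma-Poisson (NB2):
`Var = mu + alpha * mu^2`, log link, per-sample log size-factor offsets.

* **Size factors** — median-of-ratios: per-sample median of count ratios to
  the per-peak geometric mean, over peaks positive in all samples, rescaled
  to geometric mean 1. The median is taken on the ratio scale (not in log
  space; at even counts the two differ).
* **Dispersion** — per-peak raw `alpha` maximises the NB profile likelihood
  on a 62-point log-spaced grid (1e-8 to 10) with fitted means taken from
  GLM fits at the nearest of four anchor dispersions (1e-8, 0.01, 0.1, 1) —
  the mean fit varies slowly with `alpha`, so anchored profiling is
  accurate and lets the whole matrix be evaluated vectorised. A trend
  `alpha(mu) = a0 + a1/mu` is fitted to the raw values by non-negative least
  squares on inverse base means, and the final dispersion is the geometric
  mean (equal weights in log space) of raw and trend, floored at 1e-8. The
  fixed shrinkage weight is stated rather than estimated: it is testable
  and adequate at the cohort sizes this package targets.
* **GLM fit** — Fisher scoring vectorised across all peaks simultaneously
  (shared design matrix, per-peak dispersion), step-clipped for stability;
  standard errors come from the observed information matrix
  `X' diag(mu(1 + alpha y)/(1 + alpha mu)^2) X` at the optimum. For a
  saturated two-group design the fitted contrast equals the log ratio of
  group means exactly, for any dispersion — a property the tests exploit.
* **Wald test** — two-sided normal approximation `p = 2(1 − Phi(|beta/SE|))`
  on the non-intercept coefficient.
* **Multiple testing** — Benjamini–Hochberg step-up. Independent filtering
  scans baseMean-quantile thresholds (default grid 0 to 0.95 in steps of
  0.01), BH-adjusts only the surviving records at each threshold, and keeps
  the threshold maximising rejections at the target FDR (ties go to the
  smallest threshold, retaining the most records); filtered-out records
  have undefined `padj`.

### Designs and sign convention

The dichotomous design codes the non-intercept column as `I[term]`, so a
positive reported `log2FoldChange` means higher methylation at term —
equivalently, hypo-methylation in preterm placentas. This convention is
reverse-engineered from the published tables: 13 of the 21 dichotomous-model
records have positive log2FC, matching the reported 62% hypo-methylated
fraction. The continuous design uses gestational age in weeks, uncentred,
so the coefficient is a per-week log2 slope (and the intercept is an
extrapolation to week 0 — only the slope is interpreted). No covariate
adjustment is offered; multi-factor designs are out of scope.

### Deliberate simplifications

Relative to the large NB frameworks in this space there is no
count-outlier (Cook's distance) handling, no fold-change shrinkage, and a
normal rather than t reference for the Wald statistic. Exact numerical
replication of any particular framework's output is a non-goal; the tests
instead pin exact closed-form properties, oracle equivalences
(statsmodels Poisson/NB fits, brute-force BH), and operating
characteristics (FDR control, power) under the generator below.

## Synthetic data generator

The generator emulates the structure of a small placental MeDIP-seq study:

* **Cohort** — 6 preterm (GA uniform in [25, 34] weeks) and 3 term
  (uniform [37, 41]); birth weights follow a linear GA trend (~166 g/week
  around 1541 g at 30 weeks) with Gaussian noise, for the group t-test
  helper.
* **Genome** — 4 toy chromosomes of 3 Mb; BED12 genes with 2–8 exons and
  coding spans (hence UTRs and strand-aware first introns); CpG islands
  placed near ~60% of TSSs plus intergenic ones, merged to disjointness; a
  chromatin-state track with `promoter` segments at TSS ± 1 kb and random
  `enhancer` segments.
* **Counts** — for peak *i*, sample *j* the replicate-summed count is one
  NB draw with mean `sf_j * 2^(b0 + b1*I[preterm_j] + b2*GA_j)` and
  dispersion `alpha = 0.1`; it is split multinomially into the 3 replicates,
  which keeps the summed matrix exactly NB (independent per-replicate NB
  draws would change the dispersion under summation — rejected). Size
  factors are log-uniform in [0.5, 2] to exercise normalisation. Baselines
  `2^b0` are log-uniform in [200, 5000], anchored so a term-reference
  sample (GA 39) has the nominal baseline.
* **Planted effects** — 5% of peaks carry a group effect `b1 = ±1.5` (log2),
  5% a per-week slope `b2 = ±0.08`, 2% both, signs independent and
  equiprobable; all other effects are exactly zero and recorded in a truth
  table. GA is sampled within the group ranges with no added confounding
  beyond the structural one (preterm ⇒ lower GA), which intentionally makes
  the two designs partially agree, as in real cohorts. Because signs
  are independent, a "both"-class peak's slope can partially cancel its
  group effect.
* **Peak calls** — each replicate's BED contains every true peak
  independently dropped with probability `replicate_dropout` (default 0)
  and with edges jittered by up to 25 bp; inter-peak gaps (≥ 500 bp) exceed
  twice the jitter so consensus regions map one-to-one onto true peaks.

Defaults are chosen for test power at the published cohort shape (n = 9),
not for biological realism: the generator has no GC or mappability bias,
no copy-number structure, no correlated peaks, and no read-level
representation, so passing tests demonstrate correctness of the inference
machinery under its own model assumptions, not robustness to artefacts of
real MeDIP-seq libraries.

## Annotation

DMRs are classified by their midpoint with fixed precedence: promoter bins
(≤ 1 kb, 1–2 kb, 2–3 kb upstream of the strand-aware TSS), then 5′ UTR,
3′ UTR, exon, first intron (transcript order), other intron, downstream
(≤ 3 kb past the transcript end), and distal intergenic as fallback.
Midpoint classification is a stated simplification (whole-region rules
differ only at category boundaries). The nearest gene minimises
midpoint-to-TSS distance (zero inside a transcript); ties break to the
lexicographically smaller symbol; chromosomes without genes yield `NA`.

CpG shores are the 0–2 kb island flanks and shelves the 2–4 kb flanks,
computed by interval expansion and subtraction so that island > shore >
shelf precedence holds and the three sets are pairwise disjoint for any
island layout (property-tested against a per-base labelling oracle).

The genome is tiled into 500-bp windows (final partial tile kept); a
window is flagged for a feature on ≥ 1 bp overlap. The enrichment score of
a feature for a DMR set is

    (fraction of DMRs overlapping feature-flagged windows)
    / (fraction of all windows flagged)

computed separately for hyper- and hypo-methylated DMRs. Overlap is
mediated through flagged windows, not direct DMR∩feature intersection —
the two differ at window boundaries, and the window-mediated form is the
one this pipeline defines. No significance test is attached to enrichment
scores.

## Gene-set comparison

Cross-model comparison matches DMRs on exact canonical location. Gene-set
over-representation uses the upper-tail hypergeometric
`P(X ≥ observed)` with `expected = |query|·|set|/|universe|`; symbols match
exactly after upper-casing (no alias resolution). The universe is the
caller's choice (default: all gene-model symbols); published analyses of
this kind rarely state theirs, which is the main caveat when comparing
p-values.

## Problem sizes and numerics

Tests and the acceptance script run at 2000 peaks × 9 samples (single
fits complete in well under a second; 20-run null batteries in a few
seconds). GLM convergence is declared at a max coefficient step below
1e-10 within 100 iterations; non-converged peaks are flagged and excluded
from testing rather than raising. Peaks with zero baseMean get undefined
p-values. All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds reproduce byte-identical
bundles and result tables.

## Known limitations

* Wald normal approximation is anti-conservative at very small counts; the
  independent filter removes most such peaks, and the null simulations
  confirm FDR control at the default settings, but extreme designs (fewer
  samples, much lower depth) are untested territory.
* The dispersion trend `a0 + a1/mu` is cruder than gamma-GLM trend fitting;
  it is monotone and adequate at these scales but can misfit genomes with
  strongly non-monotone mean-dispersion structure.
* Midpoint-based annotation and TSS-distance nearest-gene assignment are
  simplifications; isoform-aware annotation is out of scope.
* The replicate-consensus rule treats "present" as any-overlap; peak
  callers that fragment peaks can therefore rescue a region via a sliver
  of overlap.
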