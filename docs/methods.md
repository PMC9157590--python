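# Methods

## Scope and model overview

senoscreen implements the computational spine of an anti-aging compound
study in five analysis layers plus a synthetic-data layer that generates
every input the analyses need:

1. **Signature/connectivity screen** — build an aging gene signature from a
   two-group expression matrix and rank compound profiles by how strongly
   they reverse it (Connectivity-Map logic).
2. **Reversal analysis** — intersect DEG sets from a senescence-induction
   contrast and a drug-treatment contrast and classify per-gene reversal.
3. **Survival analytics** — Kaplan–Meier curves, mean lifespan, percent
   extension, Wilcoxon rank-sum and Mantel–Cox log-rank comparisons for
   mouse cohorts.
4. **Yeast replicative lifespan** — division counting, cycle-duration
   statistics and condition comparisons from mother-cell budding timelines.
5. **Phenotype scores** — closed-form behavioral, plate-reader and
   histology formulas.

## DEG calling and the aging signature

Genes are called differentially expressed between two groups with a
two-sided Welch (unequal-variance) t-test on log2 expression, passing iff
the linear fold change exceeds **1.20** in either direction
(|log2FC| > log2 1.20 ≈ 0.263) *and* raw p < **0.05**. The double
threshold is deliberately gated on raw p-values, which is the convention
the screen emulates; Benjamini–Hochberg q-values are emitted alongside
because the raw-p pass set carries an appreciable false-discovery load at
small n (at 6v6 with 10% true effects, roughly a quarter of passing genes
are nulls, while the q < 0.05 subset controls FDR below 10% — both
properties are exercised in the tests). Genes with zero variance in both
groups and equal means receive p = 1 by convention.

The signature keeps all passing genes per direction up to `max_per_side`
(default 150), preferring smallest p with lexicographic gene-id
tie-breaks, and errors if either side is empty — a one-sided signature
cannot be scored.

## Connectivity statistic

For a tag set with t members at 1-based ranks pos(1) < … < pos(t) in a
profile of N genes, the enrichment score is the classic unweighted
max-deviation (Kolmogorov–Smirnov) statistic

    a = max_j [ j/t − pos(j)/N ],   b = max_j [ pos(j)/N − (j−1)/t ]
    ES = a if a ≥ b else −b

computed with integer numerators over the common denominator t·N so the
a ≥ b comparison — including exact ties, which return +a — is not subject
to float rounding. Two consequences of this finite-N form are documented
rather than "fixed": the extreme top arrangement scores 1 − t/N (not 1),
and reversing a profile mirrors the score only to within one 1/N rank
step, with the sign flip guaranteed only when one side dominates by more
than one step.

The two-sided **anti-aging score** evaluates ES for the signature's up and
down sets separately. If the two enrichments share a sign the profile is
incoherent and scores 0; otherwise `raw = es_up − es_down` and the score
is `−raw/2`, so **positive means reversal** of the signature (signature-up
genes pushed down the profile, signature-down genes up) and +1 is the
large-N limit of perfect reversal. Signature genes absent from a profile
are dropped with a warning; fewer than `min_overlap` (default 3) matched
genes per side is an error.

**Permutation p-values** redraw random disjoint tag-set pairs of the same
sizes and count null |score| ≥ |observed| with an add-one correction,
`p = (1 + k)/(1 + n_perm)`. Because the unweighted statistic depends on a
profile only through (N, t_up, t_down), one null sample per size triple is
drawn and shared across compounds — statistically identical to
per-compound resampling at ~1/n_compounds the cost. Ranking is by
descending score with perm-p then compound-id tie-breaks, so it is a
deterministic permutation of 1..n.

## Reversal analysis

Shared genes are the intersection of the two passing sets; a gene is
*reversed* iff its two fold changes disagree in sign (zero fold change
counts as not reversed and is logged). No magnitude criterion is applied
by default — passing genes already clear the fold-change gate — but an
optional `require_magnitude` filter exists. The shared-gene table is
emitted ordered by the first contrast's fold change, ready for a heatmap;
no clustering is implied. On independent null inputs the reversed
fraction concentrates at 0.5 (binomial), which the tests verify.

## Survival analytics

Displayed curves use the Kaplan–Meier product-limit estimator (via
lifelines), which reduces to the empirical survivor function without
censoring. `mean_lifespan` refuses censored cohorts — an arithmetic mean
is biased there — and points the caller to a restricted-mean analysis.
Percent extension is `100·(treated − control)/control` rounded
half-away-from-zero to one decimal, matching the one-decimal convention
of reported extensions (394→479 days = 21.6%, 874→959 = 9.7%). The
Wilcoxon rank-sum test uses exact enumeration when the pooled sample is
at most 12 with no ties (e.g. {1,2,3} vs {4,5,6} → p = 0.1 exactly) and
the normal approximation with tie and continuity corrections otherwise;
the log-rank test is the standard 1-df Mantel–Cox statistic.

## Yeast replicative lifespan

A mother's RLS is its number of budding events; cycle durations are
successive bud-time differences (a mother with one bud contributes no
durations). The division-indexed survival curve is a product-limit
estimate over division number, so mothers censored by the end of the
imaging window are handled; without censoring it equals the empirical
tail frequency P(RLS ≥ k) exactly. The short-cycle fraction counts
durations **≤ 1.4 h (inclusive)**. Cycle-length *heterogeneity* is
summarized as the coefficient of variation of pooled durations — the
source analysis reports decreased heterogeneity without naming a metric,
and CV is scale-invariant. RLS extension between conditions reports the
percent change of mean (and median) division count with a Wilcoxon
rank-sum p on the per-mother counts.

## Synthetic data: what it emulates and what it does not

All generators fan a single user seed into fixed per-generator child
streams (`default_rng([seed, stream])`), so outputs are bit-for-bit
reproducible and adding a generator never perturbs the others. Planted
truth labels are always returned.

- **Expression**: per-gene baselines N(8, 2) on the log2 scale with
  i.i.d. Gaussian noise (SD 0.3 by default); exactly `n_de_genes` genes
  (default 100 of 1000) get a ±1 log2 mean shift in the old group, half
  up and half down, at 6 samples per group. This matches the additive
  log-scale model the fold-change threshold assumes but has no
  gene–gene correlation, library-size variation or count-level
  mean–variance structure, so DEG power measured here is optimistic
  relative to real RNA-seq.
- **Compendium**: every profile covers the full gene universe with
  i.i.d. N(0, 1) differential scores; reversers subtract/add a
  `reversal_strength` (default 2) shift on signature-up/-down genes,
  mimickers the opposite, nulls nothing. Profiles are exchangeable noise
  apart from the planted shift — there is no shared cell-line response or
  batch structure, so top-k recovery here demonstrates the scoring
  machinery, not robustness to correlated compendia.
- **Mouse lifespans**: Gompertz law of mortality (hazard a·e^{bt}) with
  b = 0.01/day and a = 1.15e-4/day, chosen once so the control mean is
  ≈394 days; treatment multiplies the time axis (accelerated-failure
  form), making the expected mean ratio exactly `treatment_effect`
  (default 1.216). Default cohort sizes are 19 control vs 10 treated.
- **Yeast timelines**: division count K geometric with mean 25
  (memoryless per-division death, matching exponential-like RLS curves);
  cycle durations lognormal with median 1.5 h and σ = 0.25; 40 mothers
  per condition by default.

**Paired mode.** The lifespan and budding generators accept
`paired=True`, which drives the treated arm through the same underlying
uniforms as the control arm (common random numbers, via the quantile
transform). This pins the *sample* effect to the planted effect and is
the mode used for parameter-recovery demonstrations: with independent
arms the extension estimator's sampling error at n = 200 is ~15
percentage points for geometric division counts (CV ≈ 1) and ~3 points
for the Gompertz cohorts, which would swamp a recovery check. Paired mode
must not be used for calibration studies — the arms are then dependent by
construction — and the calibration tests use the default independent
mode.

## Numerical choices and degenerate inputs

- KS statistic: exact integer tie-break (above); ties in profile scores
  broken lexicographically by gene id at ranking time.
- Welch t-test NaNs (zero variance in both groups): p = 1 if the means
  agree, p = 0 otherwise.
- Percent extension rounding: decimal half-away-from-zero at one decimal.
- Wilcoxon: exact path requires pooled n ≤ 12 *and* no ties; otherwise
  the tie-corrected normal approximation with continuity correction.
- Empty cycle-duration sets and all-censored cohorts raise rather than
  return NaN silently; a zero fold change on a shared reversal gene is
  logged and counted as not reversed.
- Tubule-injury rubric boundaries (20, 40, 60, 80%) fall into the upper
  bin (lower-closed intervals), consistent with "≥80%" being the top
  score; 0% means score 0 and anything in (0, 20) scores 1.
- Y-maze entries are scored as recorded; re-entries into the same arm
  are not collapsed, and an alternation is any window of three
  consecutive entries visiting three distinct arms.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run everything on synthetic
data at desk scale: 1000-gene matrices at 6v6, a 110-compound compendium
with 1000 permutations, 1000-replicate null calibrations at cohort sizes
19 vs 10, and 200-subject/200-mother recovery runs. These sizes keep the
whole suite within a few minutes on one CPU while leaving the binomial
error of the calibration rates well inside the tested bands.

## Known limitations

- The screen is validated on planted synthetic truth; no attempt is made
  to reproduce any published compound ranking, whose input compendium is
  not deposited.
- The published 352-gene intersection and the yeast dose–response
  extension percentages (14.6–48.9%) likewise depend on undeposited raw
  data; the reversal and RLS modules are validated by property tests
  (null fraction 0.5, planted negation, epistasis harness) instead.
- Weighted GSEA (score-weighted running sum), multi-cell-line tau
  summarization, Cox/frailty models and maximum-lifespan statistics are
  out of scope.
- The one-decimal reported extension of a premature-aging cohort
  (19→29 days) is arithmetically 52.6%, not the published "approximately
  53.8%"; the package takes no position and simply computes the formula.
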