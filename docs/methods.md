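# Methods

## Design and quantities

The study design is a 2×2 cross of genotype (wild type vs PepT1 knockout)
and small-intestinal compartment (villus vs crypt), giving four groups —
WTV, WTC, KOV, KOC — with n = 4 biological replicates each on the miRNA
panel.  Four fixed pairwise comparisons are analysed throughout:

| label     | first | second | reads as                    |
|-----------|-------|--------|-----------------------------|
| `wt_axis` | WTV   | WTC    | crypt vs villus in WT       |
| `ko_axis` | KOV   | KOC    | crypt vs villus in KO       |
| `villi`   | WTV   | KOV    | KO vs WT within villi       |
| `crypts`  | WTC   | KOC    | KO vs WT within crypts      |

Direction calls always describe the second group relative to the first,
so "up" on an axis comparison means crypt-enriched.

## qPCR quantification

**Inclusion QC.** A reaction is kept iff Cp < 37 and the no-template
negative control amplifies at least 5 cycles later.  Both bounds are read
strictly as stated: Cp = 37.0 fails, a 4-cycle margin fails, a 5-cycle
margin passes.  A negative control that never amplified is treated as
amplifying at the 40-cycle detection cap — the most permissive reading
consistent with the rule.  A missing Cp is "undetected", not an error.

**Global-mean normalization.** For sample *s* and assay *a*,

    value(a, s) = mean over common assays of Cp(·, s) − Cp(a, s)

where the *common* set is the assays passing QC in every sample.  Higher
values mean more expressed, and any per-sample constant Cp offset cancels
exactly (this shift invariance is tested as an exact identity).  If no
assay is detected everywhere the step fails loudly; an explicit fallback
flag relaxes the normalizer set to assays detected in ≥ 90 % of samples,
using in each sample only the normalizers actually detected there — no
values are imputed, because silent imputation would change downstream
selection.

**Linear signal.** The selection rule below thresholds a linear-scale
"signal".  We define signal = *A*·2^value with a configurable anchor *A*
(the signal of a panel-average assay).  The anchor is a property of the
data source, not of the method; the synthetic generator plants its own
anchor (32768) large enough that detectability, not the anchor, decides
which planted features are seen.

**ΔΔCt.** fold = 2^−ΔΔCt with ΔΔCt = (Ct_target − Ct_ref)_test −
(Ct_target − Ct_ref)_control.  Missing terms raise an error naming the
term.

## Differential expression and gradients

Each feature is compared in the four comparisons with an equal-variance
two-tailed Student's t-test on the linear signal vectors (Welch's test is
available behind a flag).  A feature-comparison is **selected** when
p < 0.05 and the larger group mean exceeds 500 on the linear scale.  No
multiple-testing correction is applied by default, matching the panel
convention the pipeline reproduces; Benjamini-Hochberg adjusted p-values
can be added per comparison with `adjust="bh"`.  Features with fewer than
two detected replicates in a group are flagged `insufficient_replication`
and excluded from selection rather than imputed.  Constant identical
groups are an exact null and are assigned p = 1.

**Gradient calls.** Group levels are arithmetic means of detected
replicates, rescaled to a baseline group.  A comparison's direction is

    up    iff  second/first ≥ τ
    down  iff  first/second ≥ τ
    same  otherwise,

with τ = 1.45 by default.  τ was fixed by calibration against the
reference pair table bundled with the package: it is the threshold band
(roughly 1.43–1.47) that reproduces the verbal gradient descriptions
accompanying those levels in 15 of 16 comparisons.  The one irreducible
exception is miR-221-3p in WT, whose tabulated crypt level (1.22×) is
described as a gradient in one place and as "equal" in another; no single
τ satisfies both, and the default follows the tabulated levels.  The
WT→KO change of the axis call is categorized as *reversed* (strictly
opposite), *preserved* (equal, non-flat), *lost* (WT gradient flattens),
*gained* (KO gradient appears), or *preserved-null* (flat in both).

**PCA overview.** Features are ranked by variance across samples (ties
broken lexicographically by id for determinism), the top 50 retained,
rows mean-centered, and the samples' first two principal components
reported.  Component signs are arbitrary.

## 2D-DIGE spot tables

The pipeline starts from DeCyder-style spot tables, not gel images.  The
signed average fold change has magnitude ≥ 1; the sign convention —
negative = higher in the second-listed condition, hence trend "Up" — was
inferred from the 40 published rows of the four identified-spot tables
bundled as reference data, every one of which is consistent with it (a
fixture test locks this).  Candidate listing uses |fold| > 1.75 and spot
selection |fold| > 2.0; the manual picking criteria applied in the
original workflow (gel position, spot reliability) are not reproducible
and are replaced by an explicit picked-spot list when needed.

For integration, each gene's axis folds are expanded into relative levels
anchored at the villus of each genotype.  The two genotype blocks carry
independent scales, so DIGE-derived protein profiles are comparable on
the two axis comparisons only; profiles transcribed from a cross-genotype
table (e.g. Actb) are flagged comparable on all four.

## Inverse-expression concordance

For each (miRNA, protein) link in the target map with both profiles
measured, directions are computed per comparison at τ over the
comparisons where **both** profiles are scale-comparable.  Per comparison
the relation is `opposite`, `same` (both non-flat, identical), `one-sided`
(exactly one flat) or `both-same`.  The pair **qualifies** iff at least
one comparable comparison is `opposite` and none is `same`: repression
predicts strictly inverse movement, so any observed co-movement rejects
the link, while flat/one-sided comparisons are uninformative.  Verdicts
are invariant under independent positive rescaling of each scale block
and under jointly negating all directions (both tested).

Target maps merge several prediction algorithms.  The default combine
rule is `union` with per-link source provenance retained — the
recall-safe choice when the original aggregation rule is unknown —
with `intersection-of-k` available.

## Fraction purity

score(f) = mean villus-marker log2 expression − mean crypt-marker log2
expression.  The score is invariant to rescaling any marker column; only
the ranking matters.  The purest villus fraction is the argmax and the
purest crypt fraction the argmin, ties broken toward the extremes of the
shedding order (earliest for villus, latest for crypt) and flagged.
PepT1 is excluded from the villus-marker set for the knockout genotype,
where the transcript is ablated; marker roles are configurable.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes:

* **Cp matrix** — ~200 assays × 16 samples.  Baseline Cp uniform in
  24–30 cycles; replicate noise Normal(0, 0.5) on the cycle scale (qPCR
  noise is approximately additive in cycles); reactions beyond 37 cycles
  recorded undetected; negative controls at 40 cycles.  A fraction
  (default 25 %) of miRNAs receives a planted axis effect of 2 log2 units
  per genotype, applied as an equal-magnitude opposite-sign Cp shift.
  The per-genotype direction pattern is drawn uniformly from the eight
  patterns with at least one non-flat axis, so reversed, lost, gained and
  preserved gradients all occur.  The planted-DE count is exactly
  round(frac_de × n_mirna).
* **Spot folds** — generated directly as signed folds per comparison from
  planted protein log2 levels plus Normal(0, 0.25) log2 noise; no gel
  image simulation (the pipeline's entry point is the fold table).
  Each planted pair assigns the protein the strictly opposite direction
  pattern of its miRNA, so the pair is inversely concordant before noise.
* **Target map** — the planted links plus round(decoy_target_rate ×
  n_mirna) random decoy links (10 at defaults).  The rate is interpreted
  per miRNA, keeping the decoy load comparable to the planted load so
  precision on planted pairs remains a meaningful statistic.
* **Marker series** — 11 fractions; villus markers decay and Lgr5 rises
  by `marker_gradient_slope` log2 per fraction, noise applied after the
  trend (slope 1, zero noise gives the closed-form 2^10 first:last
  ratio).

Defaults (n = 4 replicates, 2-cycle effect, 0.5-cycle noise) put the DE
stage at near-saturated power — the expected noncentrality is ≈ 5.7
standard errors — so recovery tests are stable rather than borderline.
Measured at these conditions over 100 seeds: planted-DE recall ≈ 0.99,
null type-I error ≈ 0.05, planted-pair precision ≈ 0.9, recall ≈ 1.0
(computed by the acceptance test, not asserted here).

What the generator does **not** emulate: amplification-efficiency
differences between assays, melting-curve artefacts, correlated
biological replicate structure, batch effects between panels or gels,
compartment cross-contamination, and gel-image processing noise beyond a
lognormal fold error.  Passing recovery tests therefore demonstrates the
pipeline's correctness under its stated noise model, not robustness to
every artefact of real panel data.

## Numerical choices

* Identical constant groups: p = 1 (exact null), never NaN.
* Undetected entries are NaN end to end; group means skip them.
* Variance ties in the PCA ranking and map iteration orders are broken
  lexicographically, making every output byte-deterministic given a seed.
* The t-test is computed vectorized over features; a scalar reference
  implementation (`pairwise_de`) is kept and tested equal to it.
* Problem sizes in tests and the acceptance script (100 seeds × 200
  features for recovery, 500 replicates for purity robustness) keep the
  whole suite under a minute while leaving Monte-Carlo error well inside
  the asserted bands.

## Known limitations

* The dataset-level published counts (36 differential miRNAs, 43/72 gel
  spots, the 20/1/15-style partitions) depend on raw panel and gel data
  that were never deposited and are not reproduced; the pipeline
  reproduces the published worked examples and its own planted-signal
  recovery instead.
* "Signal strength > 500" is applied on a declared, config-anchored
  linear scale; whether the original rule was applied pre- or
  post-normalization is unknowable from the published record.
* How undetected replicates entered the original group means is likewise
  unstated; we require ≥ 2 detected replicates per group instead of
  imputing.
* The concordance filter is direction-based only; it does not model
  repression strength, nor distinguish direct from indirect regulation.
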