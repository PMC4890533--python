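# cryptvillus

Analysis pipeline for miRNA and protein expression gradients along the
intestinal **crypt-villus axis**, built around a PepT1-knockout vs wild-type
mouse design.  The small-intestinal epithelium renews continuously from
Lgr5⁺ stem cells at the crypt base toward differentiated enterocytes at the
villus tip; miRNAs and their target proteins are distributed along this
axis, and ablating the villus peptide transporter PepT1 perturbs both.
`cryptvillus` implements the computational side of such a study end to end,
for researchers analysing qPCR miRNA panels and 2D-DIGE proteomics from
compartment-separated epithelium:

1. **qPCR panel quantification** (`cryptvillus.qpcr`) — inclusion QC
   (Cp < 37 and ≥ 5 cycles below the negative control), per-sample
   global-mean normalization against the assays detected in every sample
   (value = mean common Cp − assay Cp), and ΔΔCt relative quantification
   (fold = 2^−ΔΔCt).
2. **Fraction purity** (`cryptvillus.fraction_purity`) — scores sequential
   isolation fractions by log-ratio marker enrichment (PepT1/Muc2 villus,
   Lgr5 crypt) and selects the purest villus and crypt isolates.
3. **Differential expression** (`cryptvillus.differential`) — the four
   pairwise comparisons of the 2×2 genotype × compartment design with
   two-tailed Student's t-tests; selection at p < 0.05 and linear signal
   > 500; gradient direction calls at a fold threshold τ = 1.45 and
   WT→KO change categories (preserved / lost / gained / reversed); a PCA
   overview on the 50 most variable miRNAs.
4. **2D-DIGE spot handling** (`cryptvillus.dige`) — DeCyder-style signed
   average fold changes (|fold| ≥ 1; negative = higher in the second
   condition), trend calls, candidate cutoffs (> 1.75, > 2.0), and
   expansion of folds into relative levels.
5. **Target integration** (`cryptvillus.integration`) — merges predicted
   miRNA→gene maps (union or intersection-of-k across sources) and tests
   each linked pair for **inverse-expression concordance**: a pair
   qualifies iff the miRNA and protein move in strictly opposite
   directions in at least one scale-comparable comparison and never in the
   same direction.
6. **Synthetic data** (`cryptvillus.synthetic_data`) — a generator with
   planted axis effects, dropout, negative controls, marker gradients and
   true miRNA-protein pairs, so recall/precision of every stage is
   measurable without access to raw panel or gel data.

A `cryptvillus` command-line tool (`simulate`, `qc`, `normalize`, `purity`,
`de`, `spots`, `integrate`, `run-all`) wraps the library; all tables are
TSV and every run writes a JSON manifest.

## Worked example

The package ships the published identified-spot tables and the four
validated miRNA-protein pairs as reference data.  Evaluating the
transcribed four-group levels (WTV, WTC, KOV, KOC) through the
inverse-concordance filter at τ = 1.45 — together with six constructed
decoy links — recovers exactly the four real pairs:

```python
from cryptvillus.datasets import reference_case_with_decoys
from cryptvillus.integration import integrate

mirna, protein, tmap = reference_case_with_decoys()
report = integrate(mirna, protein, tmap)
print(f"{len(report.verdicts)} links evaluated, {len(report.qualifying)} qualify")
for v in report.qualifying:
    print(f"  {v.mirna:<12} -> {v.gene:<10} ({v.reason})")
```

```
10 links evaluated, 4 qualify
  miR-33-5p    -> Gyk        (opposite in wt_axis, ko_axis)
  miR-221-3p   -> Serpinb1a  (opposite in ko_axis)
  miR-200c-5p  -> Rpsa       (opposite in wt_axis)
  miR-212-3p   -> Actb       (opposite in villi, crypts)
```

Reading the first line: miR-33-5p is crypt-depleted in both genotypes
while its predicted target glycerol kinase is crypt-enriched in both — an
inverse relation on both axis comparisons, so the link qualifies.  The
Actb pair instead qualifies through the cross-genotype comparisons (both
features are flat along each axis but move oppositely between genotypes).

An end-to-end simulated run with planted ground truth:

```python
from cryptvillus.pipeline import RunConfig, run_pipeline
from cryptvillus.synthetic_data import SimConfig

manifest = run_pipeline(RunConfig(outdir="demo", simulate=SimConfig(seed=42), seed=42))
print(manifest["summary"])
```

prints, among other fields,

```
planted_de_recall = 0.98        # 49/50 planted miRNAs recovered
null_type_i_rate = 0.038        # false-positive rate on unplanted features
pair_precision = 0.83           # qualifying links that were truly planted
pair_recall = 1.0               # planted pairs recovered
purest_villus_fraction = 1      # first fraction = purest villus isolate
purest_crypt_fraction = 11      # last fraction = purest crypt isolate
```

## Documentation

`docs/methods.md` describes the statistical model, the defaults and their
rationale, what the synthetic generator does and does not emulate, and
known limitations.
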