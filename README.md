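# ucbranch

Multi-omic analysis of urothelial bladder cancer progression, built as a
reusable, tested Python pipeline.  It covers the computational chain used
to argue that invasive bladder tumors arise from two distinct precursor
branches — papillary urothelial cancer (PUC) and flat carcinoma in situ
(CIS) — and that the CIS-derived branch behaves more aggressively:

* **Label-free proteomic quantification** — in-silico tryptic digestion,
  iBAQ (summed peptide intensity over the count of theoretically
  observable peptides), FOT normalization (iBAQ / total iBAQ × 1E5,
  floored at 1E-5), retention-time regression for match-between-runs
  transfer, a strict >30% detection filter, floor imputation and log2
  transform.
* **Single-sample enrichment (ssGSEA)** — weighted running-sum scores
  (weight 0.75, rank normalization, area under the running enrichment
  score, permutation-normalized NES), plus derived scores: a DNA-damage-
  response (DDR) score from standardized phospho abundances and
  regulon/TF activity over target-gene sets (minimum size 10).
* **SBS mutational signatures** — 96-trinucleotide-context catalogs on
  the pyrimidine strand, de novo NMF extraction (multiplicative updates,
  generalized KL divergence), and NNLS refitting against a reference
  signature set with the 0.08 weight filter and dominant-signature
  grouping.
* **Copy-number burden** — length-weighted arm-level aggregation of
  segment log2 ratios, amp/del calls at |log2| ≥ 1, Fisher tests of
  alteration frequency between groups, and CNA→protein cis-effect
  screens.
* **Origin classifier** — a differential protein panel (Wilcoxon,
  BH-adjusted p < 0.05, fold change > 2 or < 0.5), an L2-regularized
  logistic model fit by Newton iterations, stratified 80/20 split with
  10-fold cross-validation, and assignment of invasive tumors to
  PUC-derived vs CIS-derived.
* **Survival analysis** — Kaplan-Meier, log-rank, univariate Cox
  (Breslow ties), and maximally selected cutpoints with permutation-
  corrected significance.
* **Synthetic cohort generator** — a seeded multi-omics cohort spanning
  Normal → Hyperplasia → UPUMP → Papilloma → LGPC/HGPC → CIS → invasive,
  with branch-discriminating protein panels, abundance-dependent
  missingness, HRAS-hotspot papillomas, class-dependent signature
  exposures, an 8p12 deletion enriched in metastatic tumors, and
  proportional-hazards survival — so every stage is testable offline.

All statistical primitives (exact/approximate Wilcoxon rank-sum,
Kruskal-Wallis, Fisher's exact 2×2, Benjamini-Hochberg, Spearman) are
implemented in `ucbranch.stats` and validated against enumeration
oracles in the test suite.

## Worked example

Run the whole pipeline on the default synthetic cohort (96 samples, 12
per histology class, 600 proteins):

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

which prints, for example:

```json
{
  "cv_accuracy": 0.896551724137931,
  "n_samples": 96,
  "panel_size": 8,
  "recovery": {
    "estimated_hr": 0.7107378024530953,
    "exposure_mean_abs_error": 0.043529134219652814,
    "origin_label_accuracy": 0.75,
    "panel_recall": 0.3888888888888889,
    "true_hr": 2.0
  }
}
```

Reading the numbers: on this small default cohort the differential panel
recovers 8 of the 18 branch-discriminating proteins (recall 0.39 against
the generator's ground truth), 10-fold cross-validated accuracy of the
PUC-vs-CIS classifier is 0.90, refit signature exposures are within 0.044
mean absolute error of the true mixtures, and 75% of invasive samples
are assigned to their true origin branch.  The hazard-ratio estimate is
noisy at 12 invasive samples (true 2.0); the survival and classifier
recovery guarantees at the sample sizes the method assumes are exercised
by `tests/test_acceptance.py`.

The same computation is available as a CLI:

```bash
ucbranch simulate --outdir sim --seed 1      # write a synthetic cohort
ucbranch run --outdir out --seed 1           # full pipeline, synthetic mode
ucbranch quantify --peptides sim/peptides.tsv --fasta sim/proteins.fasta \
    --out protein_matrix.tsv
```

Library use mirrors the CLI; every stage is a plain function:

```python
from ucbranch import CohortConfig, generate_cohort, refit_signatures

bundle = generate_cohort(CohortConfig(seed=1))
bundle.write("sim/")
```

## Acceptance script

`python scripts/acceptance.py --seed <int> --out <path>` regenerates the
default synthetic cohort from the seed, executes every pipeline stage
(quantification → enrichment → signatures → CNA → panel → classifier →
derived-group comparisons), prints a summary of the recovery table, and
writes the JSON result file.  The quantitative acceptance checks —
oracle equivalence, conservation laws, signature and classifier
recovery, statistical calibration, and byte-level determinism — live in
`tests/test_acceptance.py` and run with the ordinary test suite.

## Input formats

Peptide evidence, abundance matrices, clinical tables, MAF-like mutation
tables (with explicit flanking bases, so no reference genome is needed),
SEG segment files (1-based inclusive on disk, converted internally to
0-based half-open) and GMT gene sets — all plain TSV/GMT/JSON/FASTA.
See `docs/methods.md` for the model, parameter defaults and the
assumptions behind the synthetic cohort.
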