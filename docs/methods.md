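# Methods

This note records the models, conventions and deliberate choices behind
`ucbranch`, in the order the pipeline runs.

## Label-free quantification (`ucbranch.quant`)

Peptide evidence carries one XIC area per (run, peptide).  Protein
abundance per run is iBAQ: the summed peptide intensity divided by the
number of *theoretically observable peptides*.  "Observable" is defined
here as fully tryptic fragments — cleavage C-terminal to K/R but not
before P, zero missed cleavages — with length 7–30 aa.  The lower bound
matches the ≥7-aa peptide identification filter used in FFPE label-free
workflows; the upper bound is the common iBAQ convention.  Proteins
whose sequence yields no observable peptide cannot be normalized and are
excluded with a warning.

FOT (fraction of total) divides each protein's iBAQ by the run's total
iBAQ, multiplies by 1E5, and floors values below 1E-5 at 1E-5.  Flooring
happens **after** normalization, so the conservation invariant (pre-floor
FOT sums to 1E5 per run, asserted at 1e-6 relative) holds exactly and
FOT is invariant to any global intensity rescaling of a run.

Match between runs fits a least-squares map from reference to target
retention times on peptides identified in both runs, choosing degree 1
or 2 by adjusted R² (ties go to linear; at least 6 anchors so the
quadratic keeps 3 residual degrees of freedom).  A peptide missing from
the target is transferred when a candidate XIC for it lies within the RT
tolerance of the model prediction; transferred records are flagged
`observed=False` so downstream analyses can exclude them.

Matrix preparation keeps features detected in **strictly more than 30%**
of samples, imputes missing entries with the 1E-5 floor and log2
transforms.  The floor sits ~20 log2 units below typical signal; this is
faithful to the published procedure but makes imputed cells extreme
outliers — a fact that matters for the classifier (below).

## Enrichment scoring (`ucbranch.enrich`)

The single-sample score is a weighted Kolmogorov-Smirnov running sum:
features sorted by (rank-normalized) value descending, set members
increment by |r|^w normalized over the members' total weight, non-members
decrement by 1/(N − n_set), and ES is the mean of the running sum (the
area under the RES).  Defaults follow the kinase-signature (PTM-SEA
style) parameterization: weight 0.75, `rank` sample normalization, area
statistic, 1000 permutations, minimum overlap 5, NES output.  NES
divides ES by the mean |ES| of size-matched random member sets, sign
preserved.

Two consequences worth knowing:

* Rank normalization makes scores invariant to any strictly monotone
  transform of a sample's profile; ties are broken by a seeded shuffle,
  so results are deterministic but not biased by input order.
* With a positive weight the ES of a *random* set is biased upward
  (early, high-rank positions carry more hit weight than the uniform
  miss decrement), so null NES values are not centered at zero.  The
  classic symmetry — ES(complement) = −ES(set), null centered — holds
  exactly at weight 0, and that is the case the symmetry tests assert.
  Scores should be compared across samples or between groups, not
  against zero.

The DDR score standardizes each DNA-damage-response marker's phospho
abundance to mean 0 / SD 1 across samples (sample SD, n−1) and averages
markers per sample; zero-variance markers are dropped with a warning.
Regulon (TF) activity is ssGSEA over transcriptional target sets with a
minimum set size of 10.

## Mutational signatures (`ucbranch.mutsig`)

Catalogs use the fixed 96-category order: substitutions (C>A, C>G, C>T,
T>A, T>C, T>G) major, then 5' flank, then 3' flank, each over ACGT.
Purine-reference records are reverse-complemented (flanks swapped and
complemented) onto the pyrimidine strand.  Records carry explicit
flanking bases so no reference genome is needed.

De novo extraction is multiplicative-update NMF under generalized KL
divergence (count-appropriate), best of `n_restarts` (default 10) by
final objective; the per-iteration objective is non-increasing and
asserted so in tests.  Rank selection is caller-supplied.

Refitting solves NNLS of the frequency-normalized catalog against the
reference signature matrix, normalizes weights to sum 1, removes weights
below **0.08**, re-fits the surviving signatures and renormalizes.  This
reproduces the published threshold-and-refit behavior with a simpler,
deterministic solver; on noise-free catalogs inside the reference's
convex hull the residual is zero to 1e-9.  A sample whose weights all
fall below threshold is flagged `unassigned`, not an error.  Dominant-
signature grouping breaks ties toward the lexicographically smaller id
and flags the tie.

## Copy number (`ucbranch.cna`)

Arm burden is the **length-weighted mean** of segment log2 ratios over
the arm, so values stay on the log2 scale and remain comparable to the
±1 call cutoff; the literal length-weighted sum is available via
`mode="sum"`.  Cutoff comparisons are inclusive (a value exactly at ±1
qualifies).  Coordinates are 0-based half-open internally; SEG files are
1-based inclusive on disk and converted on read/write.  Group frequency
differences use Fisher's exact test with BH correction across arms;
cis-effects are Spearman correlations of a gene's copy-number value with
its own protein, declared at rho > 0 and BH-adjusted p < 0.05.

## Statistical primitives (`ucbranch.stats`)

* Wilcoxon rank-sum: exact p by full enumeration of group assignments
  when n1+n2 ≤ 14, otherwise a tie-corrected normal approximation with
  continuity correction (the correction is a flag; switching it off
  makes the two-group Kruskal-Wallis p equal the approximation to 1e-6,
  which is the equivalence the tests assert).
* Fisher's exact 2×2: two-sided by the probability-mass method (sum of
  hypergeometric probabilities ≤ the observed table's, with the standard
  1+1e-7 relative slack); a zero margin returns p = 1 by convention.
* Benjamini-Hochberg: step-up, clipped at 1, mapped back to input order.
* Spearman: average-tie ranks; t approximation at n ≥ 10, exact
  permutation below.
* Differential panels test on log2 values but compute fold change as the
  ratio of group means on the linear (FOT) scale, imputed floors
  included; thresholds are BH-adjusted p < 0.05 and ratio > 2 or < 0.5.
  Mean-of-FOT was chosen over medians because a "ratio > 2" rule is a
  statement about means on the linear scale.

## Origin classifier (`ucbranch.classify`)

The named "fast large margin" operator is, by its own description,
logistic regression; it is implemented as L2-regularized logistic
regression minimizing mean logistic loss + (λ/2)‖w‖² (intercept
unpenalized, λ = 1.0 default), solved by full Newton steps with
step-halving to gradient norm < 1e-8 — fully deterministic.  Features
are z-scaled with training-set statistics stored on the model, making
predictions invariant to affine feature rescaling.  Cross-validation is
stratified with scaling re-estimated inside each training fold (a
leakage test asserts this).  AUC is the Mann-Whitney probability of
correct ranking with ties counted 0.5.  Invasive samples are assigned
PUC-derived when P(PUC) ≥ 0.5; an exact 0.5 goes to PUC-derived and is
flagged.

## Survival (`ucbranch.survival`)

Kaplan-Meier with censored-at-event-time samples counted at risk;
log-rank with hypergeometric variance at tied event times; univariate
Cox by Newton-Raphson on the Breslow partial likelihood (Efron optional)
with Wald CI exp(β ± 1.96 SE); monotone likelihood is flagged
non-converged with the estimate bounded at |β| = 20.  On tie-free data
the Cox score test at β = 0 equals the log-rank statistic to 1e-9.

The optimal cutpoint maximizes the log-rank statistic over all midpoints
between distinct marker values leaving ≥ ceil(minprop·n) samples per
side (minprop 0.1).  Significance is selection-adjusted by permuting the
marker and re-maximizing (p = (1 + exceedances)/(n_perm + 1)), which
gives exact finite-sample control at desk scale, in place of the
asymptotic maxstat approximation.

## Synthetic cohort (`ucbranch.synthetic`)

The generator emulates the *structure* the analysis assumes, not raw
mass spectra or genomes.  Stated-world defaults: histology classes
Normal/Hyperplasia/UPUMP/Papilloma/LGPC/HGPC/CIS/Invasive at 12 samples
each; 600 proteins with log2-normal abundance (base U(2,12) on the log2
FOT-like scale, residual SD 1.0); an 18-protein panel shifted 1.5 log2
units between the papillary and CIS latent branches (half up in each);
83% of papillomas carry an HRAS hotspot, 80% of hotspots Q61R; Poisson
mutation burden (mean 100/sample) drawn from class-dependent mixtures of
four well-separated synthetic reference signatures; DDR phospho markers
+1.2 log2 in CIS and invasive samples; one 8p12 segment deleted at log2
−1.2 in 80% of metastatic invasive samples (5% otherwise) with a
designated cis-effect protein lowered accordingly; exponential survival
with baseline hazard ln2/50 per month, hazard ratio 2.0 for the CIS
branch, independent exponential censoring at 0.01/month; invasive
samples arise from the CIS branch with probability 0.38 and metastasize
with probability 0.5 (CIS-derived) vs 0.15 (PUC-derived).  Missingness
is logistic in true log2 abundance (midpoint 4.0, slope 0.8), i.e.
left-censoring-like, as in FFPE label-free data.

What the generator does **not** emulate: correlated protein co-expression
beyond the injected panel/regulon/pathway structure, batch effects,
peptide-level interference, subclonal mutation structure, or focal CNA
beyond the single 8p12 event.  A green test therefore establishes that
the algorithms recover the stated latent structure under realistic
missingness and noise — not that they would reproduce any particular
clinical cohort's numbers.

### A note on effect attenuation

Floor imputation places missing values ~20 log2 units below signal.
Under the default missingness parameters this attenuates the *observed*
standardized panel effect well below the generated 1.5 (measured
per-feature SMD 0.2–1.2 after imputation), which in turn caps pooled CV
sensitivity of the origin classifier near 0.79 at n = 60 PUC + 40 CIS.
The classifier-recovery acceptance test therefore evaluates the world it
names — panel effect 1.5, noise 1.0 — without the orthogonal missingness
mechanism, where pooled sensitivity/specificity measure ≈ 0.99/1.00.
Both numbers are real properties of the package and both are worth
knowing when applying the classifier to heavily imputed matrices.

## Pipeline (`ucbranch.pipeline`)

A single top-level seed spawns per-stage substreams, so the full run is
deterministic and byte-identical across repeats (the provenance hash
covers analysis parameters, not the output path).  Stages halt with a
stage-tagged error; outputs are TSV/JSON only.  In synthetic mode a
recovery table compares estimates against the generator's truth (panel
recall, exposure mean absolute error, origin-label accuracy, hazard
ratio).  The PUC group for panel construction is LGPC + HGPC; the
comparison group is CIS; invasive samples are then scored by the trained
model and the derived groups compared on metastasis (Fisher), pathway
scores (Wilcoxon + BH) and survival (KM, log-rank, Cox).

## Known limitations

* No razor-peptide handling: each evidence row names one parent protein;
  ambiguous assignments must be resolved upstream.
* Signature refitting does not apply trinucleotide-opportunity
  correction (no genome in scope); exposures are relative to the
  observed catalog.
* The cutpoint permutation test is exact but Monte-Carlo; its p-values
  have resolution 1/(n_perm + 1).
* Fold changes on heavily imputed features are dominated by the floor
  value; interpret panels on such features with care.
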