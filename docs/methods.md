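# Methods

## The calibration model

The package treats each in-silico predictor, within each gene, as a scalar
classifier: a variant is called deleterious when its converted score
strictly exceeds a cutoff. Calibration is the choice of that cutoff from a
panel of labelled variants — catalogued disease mutations as cases,
population variants (with any catalogued disease variants removed by exact
variant-id match) as controls. The quality measure is the Matthews
correlation coefficient, chosen because case/control counts are heavily
imbalanced per gene (e.g. 479 disease vs 22 control mutations for *GCK*,
64 vs 185 for *ABCC8*) and MCC, unlike accuracy or F1, is symmetric in the
two classes. The convention MCC = 0 when any margin of the confusion table
is empty keeps the screen well defined at extreme cutoffs.

Records a predictor cannot score are excluded from the confusion table and
reported through a separate missing rate; FNR and FPR are therefore always
conditional on "the method returned a score". Rates are kept as proportions
internally and formatted as percentages only in human-readable output.

## Score conversion

All predictors are placed on a common "larger = more deleterious" scale
using the dbNSFP v2.3 conversion rules, implemented exactly as published,
including the literal non-D RadialSVM expression
(1 − S_o/−2.00575697514507)·0.5 — the sign is not simplified away. Two
policy decisions:

* **Ties classify as benign.** Every default threshold is stated as a
  strict ">", so a score exactly at threshold is not deleterious.
* **Out-of-range raw scores clamp to the bound** (with a warning) rather
  than being rejected: real annotation databases contain such values, and
  rejection would silently inflate missingness. A strict mode rejects
  instead.

The LRT Ω<1 condition and the MutationTaster / RadialSVM prediction-class
letters are carried as precomputed auxiliary columns, as annotation
databases supply them; only the letters A/D/N/P (MutationTaster) and D/N/T
(RadialSVM) are recognised — anything else is a hard conversion error, not
a silent reinterpretation.

## Threshold redefinition

For one (gene, method) pair the candidate cutoffs are the midpoints between
consecutive distinct pooled scores plus one sentinel below the minimum and
one above the maximum (offset by the last distinct gap). This set realises
every achievable binary split of the data exactly once, so screening it is
equivalent to an exhaustive search — the test suite asserts equality with a
brute-force oracle that tries every observed value as a cutoff. A fixed
grid would be both coarser and slower to make exact.

The method's default threshold is always appended to the candidate set,
which guarantees max-MCC ≥ default-MCC on the calibration data by
construction. Ties in MCC break toward the cutoff with higher specificity
(fewer false positives — the dominant failure mode of these predictors on
population controls), then toward the smaller cutoff.

Calibration is deliberately in-sample: the panel *is* the catalogue the
thresholds are meant to summarise, and the reports label MCCs accordingly.
No cross-validation or held-out evaluation is performed, and no consensus
threshold is derived for genes outside the calibrated set — pairs with no
scored case or control are skipped with a structured record, not an error.

## Inter-method statistics

* Spearman correlations are computed on disease-label records only,
  pairwise-complete, with average ranks for ties and two-sided p-values
  from the large-sample t approximation (`scipy.stats.spearmanr`); cells
  with fewer than 3 complete pairs are flagged rather than estimated.
* Per-gene descriptives use the sample SD (n−1; undefined and flagged for
  singleton cells) and linear interpolation between order statistics for
  quantiles — the common statistics-package convention.
* The across-gene comparison is a one-way fixed-effects ANOVA per method.
  An all-constant column returns F = 0, p = 1 by convention.
* Methods are compared by the average difference of gene-level redefined
  MCCs with a paired two-sided t-test across genes (the pairing unit is the
  gene; with 7 genes that is 6 degrees of freedom, so p-values are coarse).
  Zero-variance differences report p = 1.0 (p = 0.0 for a constant nonzero
  offset) with a degeneracy flag. No multiple-testing correction is
  applied.

## Synthetic panels

The generator emulates the *structure* of a real calibration panel, not any
particular dataset:

* **Counts.** Seven genes with the catalogued case/control counts
  (HNF4A 86/57, GCK 479/22, HNF1A 324/78, HNF1B 36/52, INS 41/14,
  ABCC8 64/185, KCNJ11 61/65; 1,091 disease mutations in total). Mutation
  classes are assigned as exact counts — 104 nonsense and 2 stop-loss among
  the cases, confined to the genes that carry them — so the analysis set
  after the class filter is exactly 985 disease mutations. The neonatal
  phenotype is assigned to 155 cases (INS 34, KCNJ11 45, ABCC8 46, GCK 30;
  the per-gene split beyond INS is a modelling choice, the 155/936 total is
  not), leaving 936 MODY cases.
* **Scores.** Truncated normals on the converted scale, one distribution
  per (gene, method) in the per-gene layout or one per method in
  the pooled layout. The family was chosen because published per-gene
  summaries report a mean and SD together with hard score bounds; a
  truncated normal honors both with four parameters. The stored mean/SD are
  the parent normal's location/scale, not post-truncation moments. One
  published SD prints as 0.000; SDs are floored at 1e-3 because a
  degenerate distribution violates the config contract.
* **Controls.** Real control score distributions are unpublished. Controls
  are drawn with the same SD as the gene's cases, centred one case-SD below
  the method's default threshold (bounds [0,1] for bounded methods,
  widened downward otherwise). This makes every default threshold a usable
  but imperfect classifier — so recalibration has something to improve —
  without fabricating estimates of real control scores.
* **Missingness** is independent, completely at random, at each method's
  published marginal rate. Real missingness is structured (e.g. predictors
  that cannot score nonsense mutations); the generator does not emulate
  that, nor catalogue ascertainment bias beyond the case/control count
  imbalance, nor the inter-method score correlations of real annotations
  (methods are drawn independently, so synthetic inter-method Spearman
  correlations reflect shared gene structure only and are much weaker than
  on real data).
* Scores are drawn on the converted scale and mapped through exact inverse
  conversion rules into raw-scale columns (with auxiliary letters/flags
  where needed), so a generated panel exercises the full conversion path of
  the pipeline.

Passing tests on these panels therefore demonstrate the correctness and
stability of the *procedure* — conversion, screening, optimization,
statistics — not the real-data performance of any predictor.

## Numerical and reproducibility choices

* All randomness flows from a single `numpy` Generator seeded from the
  config; a panel, and every report file derived from it, is byte-identical
  across re-runs with the same seed and configuration.
* The ground truth returned with each panel records, per (gene, method),
  the generating distributions and the equal-prior Bayes boundary
  (μ_case + μ_control)/2 for the equal-SD case. On imbalanced panels the
  MCC-optimal cutoff need not coincide with this midpoint. For balanced
  equal-variance panels (n = 500/class) the redefined threshold's
  distribution across seeds centres on the midpoint well within
  3σ/√n, while individual estimates scatter at the larger n^(−1/3) scale
  characteristic of empirical argmax (cutoff) estimators — the test suite
  checks both at those scales.
* Report tables are written with full float precision; percent rounding is
  a display concern. Test problem sizes (panel of ~1,500 records, 1,000
  oracle panels of ≤ 50 records, 1,000-replicate null simulations) were
  chosen to exercise every code path while keeping the default suite fast.

## Known limitations

* In-sample MCCs are optimistic; with few controls per gene (*GCK*: 22) a
  redefined threshold can overfit the particular control sample.
* The exchange format is deliberately minimal (tab-separated, "." for
  missing); there is no VCF ingestion or annotation of novel variants.
* The synthetic generator is a stand-in for structure, not a simulator of
  any predictor's real behaviour (no point mass at score bounds, no
  inter-method correlation, no class-dependent missingness).
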