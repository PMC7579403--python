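# Methods

## Problem and model

`potn` classifies 9-mer peptides (nonamers) as immunogenic or
non-immunogenic for the HLA-A2 allele. The intended training data are
peptides with experimentally verified T-cell activity in both classes;
the non-immunogenic class consists of validated HLA-A2 *binders* that
fail to elicit a response, which makes the classification genuinely about
immunogenicity rather than binding.

The classifier is an RBF-kernel support vector machine over a feature
vector assembled per peptide:

1. **Positional physicochemical descriptors (11).** Each descriptor is a
   dictionary lookup `scale[residue at position]`. The default
   descriptor set is ASA, charge, ECI, entropy, hydrophobicity, ISA,
   residue mass, transfer energy (organic solvent/water) and polarity at
   P3; transfer energy at P4; and isoelectric point at P5. The set is a
   configuration default (`name@position` list), not hard-coded.
2. **Residue propensity (10).** For residue *i* at position *j*,
   `R_ij = (P_ij − N_ij) / (P_ij + N_ij)` with `P`/`N` the
   class-conditional relative frequencies in the training set. Scores lie
   in [−1, +1]; the percentage factors sometimes used to express the
   frequencies cancel. A peptide contributes its nine positional
   propensities plus their sum.
3. **External predictor columns (7, optional).** Binding affinity (raw
   and rescaled), C-terminal cleavage, a combined processing score, and
   three peptide/MHC stability readouts, produced by external tools and
   joined on exact sequence. With no external table the model runs in
   "core" mode on the 21 internal features; the mode is stamped into the
   model and scoring refuses mismatched inputs rather than imputing.

Features are selected by a per-column two-sample Student's t-test
(pooled-variance, two-sided; Welch optional) between the classes in the
training set, retaining p < alpha with alpha = 0.05 by default. No
multiple-testing correction is applied — the filter is deliberately a raw
p-threshold. Constant columns take p = 1 by convention.

Retained columns are z-scored with mean/SD of the training rows only
(sample SD, ddof = 1; zero-variance columns map to 0). The SVM's C is
chosen from the grid {0.25, 0.5, 1, 2, 4} by leave-one-out
cross-validation (n fits on n−1 rows); ties break toward the smaller,
more strongly regularized C. The final model refits on the full training
set at the chosen C.

## Key parameter defaults

| parameter | default | rationale |
|---|---|---|
| peptide length | 9, fixed | scope is HLA-A2 nonamers only |
| train fraction | 0.6 per class | per-class rounding is half-away-from-zero; it maps a 146/214 set to 216/144 |
| alpha (feature filter) | 0.05 | conventional significance threshold |
| C grid | 0.25–4 | small grid around 1; LOO-validated |
| kernel width | "scale" heuristic, 1/(n_features·Var) | unit-variance features make this ≈ 1/n_features; the resolved value is recorded in the model file |
| class weighting | none | despite class imbalance; available as an option |
| propensity pseudocount | 0 (off) | the propensity formula has none; add-k smoothing available |
| undefined propensity cells | 0 | residue absent from both classes at a position carries no evidence |
| decision threshold | 0 on the signed decision value | positive iff score > 0 (strict) |
| screening top fraction | 0.002 | selected count is floor(N·fraction), minimum 1 |

The canonical prediction score is the SVM's signed decision value
(larger = more likely immunogenic), not a probability; values near ±1
are typical for confident calls.

## Property tables

The ten physicochemical scales ship as a plain TSV
(`src/potn/data/property_tables.tsv`) with one row per scale and a
provenance string: Chothia tripeptide ASA, side-chain net charge,
Collantes–Dunn electronic charge index and isotropic surface area,
Kyte–Doolittle hydropathy, average residue mass, Nozaki–Tanford transfer
free energy, Zimmerman isoelectric point, and Grantham polarity. The
entropy scale is a side-chain rotatable-bond count — a conformational-
entropy proxy constructed here, labelled as such in the file; users who
need a published entropy-of-formation scale can override it. Every scale
is overridable via `load_property_tables(path)`, and the provenance of
the table set used at training time is stored in the model file.

## Evaluation conventions

- **ROC/AUC.** Standard threshold sweep; tied scores advance FPR and TPR
  jointly, and the area is trapezoidal — equivalently the Mann–Whitney
  concordance probability with half-credit for ties.
- **Partial AUC.** Area under the ROC restricted to FPR ≤ cap, reported
  unnormalized (maximum = cap) with linear interpolation at the cap; a
  normalized variant divides by the cap. Vertical ROC segments (duplicate
  FPR values) are preserved, not re-interpolated.
- **Confusion metrics.** Accuracy (TP+TN)/n and precision TP/(TP+FP) at
  a stated threshold; precision is NaN with a warning when nothing is
  predicted positive.
- **Improvement rate.** 100·(new − baseline)/baseline percent.
- **Enrichment.** recovery(f) = fraction of actives among the top
  ⌈f·N⌉ of the ranking; the smallest f with full recovery is reported.
- **Binding assay.** Fluorescence index FI = (a − b)/b from mean
  fluorescence with (a) and without (b) peptide; categories are weak
  (FI < 0.5), moderate (0.5 ≤ FI < 1.5) and high (FI ≥ 1.5), half-open
  exactly at the cut-points.
- Report rounding: percentages to 2 decimals, AUC to 3.

## Screening

Proteins are cleaved by a sliding window of width 9, step 1. Windows with
non-canonical letters are skipped (logged). Exact-duplicate nonamers —
within or across proteins — merge into one record carrying every origin
as (protein id, 1-based start). Ranking is by score descending with
lexicographic tie-breaks on the peptide string for cross-platform
determinism (an include-all-ties option exists); the selected count is
floor(N·fraction). Output never writes partial files on failure.

## Synthetic data generator

The generator emulates the statistical structure the model assumes, so
every component is testable without any external dataset:

- positions sampled independently from per-position categorical
  distributions;
- both classes share anchor preferences (Leu at P2 with probability 0.5;
  Leu/Val at P9 with probability 0.3 each) — the HLA-A2 binding motif;
- the positive class is enriched at P3 (small/flexible residues A/G/S),
  P4 (aliphatic L/I/V) and P6 (aromatic F/Y/W) by configurable factors
  (defaults 3/2/2; the benchmark bundle uses 6/3/3);
- class sizes default to 146 positive / 214 negative;
- surrogate external columns are class-conditional normals with a
  configurable mean shift in SD units (default 1 SD);
- no sequence ever appears in both classes (collisions are resampled
  with a bounded retry budget).

The benchmark bundle (`make_benchmark`) additionally builds a 40-protein
toy proteome (length 100, uniform background) with ten planted epitopes.
Planted peptides are archetypal positives — anchors fixed, enriched
residue sets forced at P3/P4/P6 — and their surrogate external scores are
folded into the upper half of the positive-class distribution, so "planted
high-scoring epitope" is true by construction rather than left to
sampling luck. The bundle's external shift is 1.5 SD per column: large
enough to separate epitopes cleanly from background windows, small
enough that screened epitopes stay inside the training support of the
RBF kernel (far-out-of-support points collapse toward the decision
bias, a property of RBF extrapolation worth remembering when screening
with externally shifted scores).

What the generator does **not** emulate: inter-position dependence,
realistic amino-acid background frequencies (uniform by default,
overridable), the empirical distributions of real binding/stability
predictors, or shared sequence ancestry between peptides. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted signal — not field performance on curated immunological data.

## Numerical and design notes

- Per-class split rounding is round-half-away-from-zero — the only
  standard convention mapping 146/214 at 60% to 216/144.
- The propensity matrix is fitted on the training partition only
  (whole-dataset fitting would leak test labels); a caller can pass any
  labeled set to `fit_propensity` to mirror other protocols.
- SVM convergence tolerance is tightened to 1e-6 so fitted models are
  independent of training-row order to high precision; persisted model
  files from identical inputs are byte-identical (training metadata
  deliberately excludes timestamps for this reason).
- Leave-one-out accuracy under label permutation is centred at or
  slightly **below** 0.5, not at 0.5: with the held-out label removed,
  the remaining set majority is anti-correlated with it. The permutation
  test in the suite asserts absence of signal accordingly.
- Model files are versioned joblib archives bundling the SVM, scaler,
  propensity matrix, property tables with provenance, selected feature
  names and training metadata; loading a newer format version fails with
  a clear error.

## Problem sizes used in the automated runs

The test suite and acceptance script run entirely on generated data: the
360-peptide benchmark with its 3,680-window toy proteome for end-to-end
checks; 17,310 random unique nonamers for the top-fraction arithmetic;
100-peptide sets across 50 seeds for the zero-signal null calibration
(held-out AUC mean 0.49–0.50); and 800-per-class sets where t-test power
on every descriptor is required. These sizes were chosen so each check is
statistically decisive at a fixed seed.

## Known limitations

- Restricted to HLA-A2 and to 9-mers; no pan-allele or variable-length
  support.
- The t-test filter is univariate and uncorrected; correlated features
  (e.g. ASA/ISA/Mw at the same position) are retained together.
- Propensity estimates from a few hundred peptides are noisy for rare
  residues; rare-residue cells can reach ±1 on single observations.
  The optional pseudocount damps this at the cost of departing from the
  plain frequency-contrast definition.
- Decision values are uncalibrated; cross-model score comparisons should
  use rank-based summaries (ROC/enrichment), not raw scores.
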