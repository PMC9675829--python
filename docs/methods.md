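# Methods

This note records the statistical procedures, the synthetic-data design,
and the numerical conventions the package commits to, in the spirit of a
model-documentation page.

## Cohort definition

A subject is **diabetic** if any of four conditions holds: self-reported
physician diagnosis, self-reported diabetes medication, HbA1c > 6.5%, or
random glucose > 200 mg/dL. Diabetic subjects with self-reported type 1
diabetes, or with C-peptide < 0.5 nmol/L while on insulin treatment, are
labelled **SAID**; all other diabetic subjects are **T2D**. Non-diabetic
subjects with HbA1c in 5.7–6.4% are excluded as prediabetic; **controls**
must satisfy all four control conditions (no diagnosis, no diabetes
medication, HbA1c < 5.7%, glucose < 200 mg/dL). Self-reported gestational
diabetes excludes a subject regardless of the other criteria, and missing
required fields yield an exclusion label rather than an exception, so the
labels always partition the table.

Two deliberate boundary conventions: the inequalities are strict exactly
as written, so a subject at precisely 200 mg/dL (with non-diabetic HbA1c
and no flags) matches neither the diabetes nor the control definition and
falls into the residual exclusion label — a measure-zero case kept
deterministic rather than silently absorbed; and the diabetes rules take
precedence over the prediabetic band, so HbA1c 6.0 with a physician
diagnosis is T2D, not an exclusion.

### HOMA2

The HOMA2 computer model's internals are unpublished, so the estimator is
pluggable (`homa2.estimator`: `parametric` or `passthrough`). The default
is a documented monotone parametric approximation: with glucose `g`
(mmol/L) and C-peptide `c` (nmol/L),

    HOMA2-B  = 100 · (c / 0.55) · (5.4 − 3.0) / (g − 3.0)   [percent]
    HOMA2-IR = (c / 0.55) · (g / 5.4)                        [ratio]

calibrated so the reference input (5.4, 0.55) maps to exactly (100%, 1.0),
with inputs clamped (and warned about) outside glucose 3.5–25 mmol/L and
C-peptide 0.2–3.5 nmol/L. B rises with C-peptide and falls with glucose;
IR rises with both. Absolute calibration away from the reference is
approximate by design: no pipeline stage depends on it, because the
synthetic generator emits HOMA2 indices directly and real cohorts can
supply externally computed values verbatim through the pass-through
estimator. Glucose arrives in mg/dL in clinical tables and is divided by
18.016 at the HOMA2 boundary.

## Subtype clustering

Clustering uses the five variables (age at diagnosis, BMI, HbA1c, HOMA2-B,
HOMA2-IR) standardized to mean 0 / SD 1 on the fitting set; the moments are
stored and reapplied to held-out subjects. k-means runs 100 seeded restarts
by default, keeping the best-inertia solution. SAID rows are excluded
upstream.

**Number of clusters.** A five-member vote over k = 2..15: BIC of
full-covariance Gaussian-mixture fits (lowest), silhouette (highest),
Calinski-Harabasz (highest), Davies-Bouldin (lowest), and a within-SS
elbow (maximal discrete curvature of the inertia curve). Majority vote;
ties resolve to the smaller k. Mixtures appear only inside this vote — the
final model is always k-means.

**Labelling.** With k = 4, clusters are named by maximizing the total
inner product between center coordinates and four fixed prototype sign
patterns (SIDD: +HbA1c, −HOMA2-B, younger, leaner; SIRD: +HOMA2-IR, +BMI;
MOD: +BMI, −age; MARD: +age, small elsewhere) over one-to-one matchings
(Hungarian algorithm), which makes the naming equivariant under center
permutations.

**Stability.** Clusterwise bootstrap Jaccard: each re-run resamples rows
with replacement, refits k-means, and records for each original cluster
the best Jaccard overlap with the new clusters, computed over subject-id
sets restricted to the resampled ids; per-cluster means over re-runs are
reported against the conventional 0.75 acceptability bound. Bootstrap
refits use 10 restarts each (the default run uses 500 re-runs); on
well-separated data additional restarts change nothing measurable, and the
original model keeps the full 100.

**Transfer and ties.** Cross-cohort classification standardizes with the
*receiving* cohort's training moments, then assigns by minimum Euclidean
distance to the supplied (possibly sex-specific) centers. Nearest-center
ties break to the lowest cluster index — a measure-zero event where
determinism matters more than the choice. Partition agreement is maximized
over one-to-one label matchings via the assignment problem on the
contingency table, alongside the adjusted Rand index.

**Sensitivity analyses.** Fasting correction regresses each HOMA2 index on
fasting minutes and replaces it by residual plus the prediction at a
reference time (480 min, the 8-hour convention); a constant fasting column
degrades to a warned no-op. Confounder analysis tests each candidate
against cluster membership (chi-square for categorical, one-way ANOVA for
continuous), residualizes the five clustering variables on the significant
ones, re-standardizes, re-clusters, and reports agreement with the
original partition plus the post-correction across-cluster ANOVA p of each
variable. Sex-specific clustering reuses the ordinary fit on sex subsets.

## Omics association

Preprocessing drops features with > 90% missingness (strictly more than),
natural-log transforms, z-scores per feature over observed values, and
winsorizes to ±5 SD, in that order; non-positive observed values cannot be
logged and are demoted to missing with a warning; missing entries stay
missing and models are complete-case per feature. The log base is
immaterial after z-scoring; natural log is used.

Case-control models follow platform convention: logistic regression of
status on the feature (proteins) and linear regression of the feature on
status (metabolites), each with covariates (age, sex, and technical
covariates; BMI additionally for metabolites; fasting minutes enter
linearly), reporting two-sided Wald p-values. Perfect separation or
non-convergence flags the record with missing estimates rather than
raising. Multiple testing uses Bonferroni at alpha / m. Replication
counting takes the primary-significant features shared with a replication
cohort, re-thresholds at alpha divided by the number taken forward, and
counts sign-concordant effects.

## Subtype signatures

The two-criteria statistic: one-vs-rest two-group linear model at
Bonferroni level (denominator = features on the platform, not features ×
clusters, matching the per-platform thresholds as printed) **and** all
pairwise two-group models at nominal 0.05, unadjusted — no extra
multiplicity layer is added to the pairwise criterion. With a single
binary predictor the linear-model Wald test *is* the equal-variance
two-sample t-test, and the implementation is cross-checked against an
independent t-test oracle. SAID and controls are display-only: they appear
in normalized profiles (group mean divided by the reference subtype's
mean, normal-approximation 95% CI = (mean ± 1.96·SE)/reference mean) but
enter no test. A feature may in principle be specific to two clusters in
opposite directions; both records are emitted. Clusters with fewer than
two members get missing test flags.

PC variance explained: PCA over T2D cases (missing entries mean-filled for
the decomposition only), then per-component R² from regressing scores on
cluster-membership indicators. Signature cross-correlation is pairwise
Pearson over shared T2D cases with two-sided p-values.

## Medication enrichment

Free-text entries are normalized (lower-case, punctuation stripped,
whitespace collapsed) and matched to dictionary synonyms at whole-word
granularity, longest synonym first, so "Metformin 500mg" matches
"metformin" and "insulin glargine" beats the embedded "insulin". Matching
is exact-after-normalization; fuzzy matching is deliberately excluded to
keep behaviour auditable. Repeat entries collapse to one subject-molecule
record; unmatched strings are retained with a flag. The packaged
dictionary is a small synthetic stand-in (~40 molecules across the
A10/C07/C09/C10/B01/N02/M01/A01/A02/N06 classes); any dictionary in the
same three-column TSV (synonym, molecule, semicolon-separated ATC codes,
validated against the ATC level grammar) can be substituted.

Usage tests are two-sided Fisher exact (probability-ordering definition)
on users × group membership 2×2 tables, at molecule, ATC-2 (e.g. A10), or
anatomical-main-group level; the reported odds ratio is the conditional
(hypergeometric-MLE) estimate; zero-margin tables return p = 1 with a
NaN-flagged odds ratio. Case-control scans carry a Bonferroni column over
the scanned codes; cluster-vs-rest calls use nominal 0.05.

## Synthetic generator

The generator defines the study conditions the tests run under.

* **Clinical.** T2D cases are drawn from a 4-component Gaussian mixture in
  standardized 5-variable space with diagonal covariance (within-cluster
  covariances are not part of the emulated description) and mapped to
  physical units by a fixed affine transform (means 45 y, 32 kg/m², 7.5%,
  76%, 2.8; SDs 8, 4.5, 1.2, 30, 1.2) with clinical floors. Default
  subtype fractions (0.25, 0.05, 0.23, 0.47) make SIRD the small cluster,
  mirroring the relative subtype prevalences reported for this kind of
  cohort. Default centers follow the subtype sign patterns with pairwise
  separations of at least ~6 within-cluster SDs (within-SD 0.5) — a
  deliberately well-separated regime in which the 4-cluster structure is
  identifiable, including the 5% cluster; the preset emulates separated
  subtypes, not a borderline clinical sample. Controls are drawn to satisfy
  all four control rules by construction; SAID rows (a 109/1160 fraction
  of diabetes rows) satisfy the SAID rule; T2D cases carry a physician-
  diagnosis flag and C-peptide ≥ 0.55 without insulin treatment, so every
  generated row classifies back to its generated status.
* **Omics.** Log-normal baselines (log-mean ~ N(5,1), log-SD 0.5).
  The first 4 × 5 features are subtype-specific with a +2 log-SD shift
  (Cohen's d = 2) in their disjoint target subtype; the next 20 are
  case-control features shifted by 0.8 log-SD in all T2D cases; entries
  are masked missing-completely-at-random at rate 0.05 (no informative
  missingness mechanism is emulated). Technical covariates (lysis proxy,
  collection week, fasting minutes, tube number) are independent normals /
  categorical labels — they carry no planted confounding.
* **Medications.** Per-drug Bernoulli usage with most-specific group
  probabilities (subtype name, else t2d/said/control); entries are
  randomized case/punctuation/dose variants of dictionary synonyms.
* **Determinism.** All streams derive from `SimulationParams.seed` via
  spawned child generators; identical params give byte-identical tables.

What passing tests on this generator do **not** show: robustness to
overlapping subtype clusters, informative missingness, batch effects
beyond the listed covariates, assay chemistry, or longitudinal structure —
none of which the generator emulates. Recovery rates quoted anywhere in
the package are statements about the preset's separated regime, not about
any real cohort.

## Problem sizes and numerics

The default analysis scale is 1000 synthetic T2D cases (plus ~1700
controls) for clustering quantities and 420 cases for signature recovery,
with 500 bootstrap re-runs for stability; the test suite uses the same or
smaller sizes and fixed seeds throughout. Zero-variance columns raise by
name at standardization; degenerate Fisher tables return p = 1; k-vote
ties take the smaller k; nearest-center ties take the lower index; all
randomized procedures accept explicit seeds and are deterministic given
them.

## Known limitations

The HOMA2 approximation is monotone-faithful but not calibrated to the
reference computer model away from the reference point. The medication
dictionary is a toy; real analyses should supply a full drug-vocabulary
TSV. Borderline-cluster individuals (near-equidistant from two centers)
are assigned, not flagged — no borderline criterion is defined. The
replication-concordance machinery compares association records computed
elsewhere; it does not harmonize platforms or map identifiers beyond the
shared feature-id join.
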