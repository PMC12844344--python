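# Methods

This note documents the models and procedures implemented in
`metabotyper`, the defaults that matter, and the reasoning behind the
choices that were genuinely open.

## 1. Synthetic cohort model

The generator (`metabotyper.simulate`) emulates a targeted serum
metabolomics study of schoolchildren as a three-component mixture over
latent metabotypes `BA` (balanced), `LI` (lipid/glucose-elevated) and
`AA` (amino-acid-elevated), with default proportions 0.47/0.29/0.24.

**Distributions.** Each analysis variable is driven by a standardized
latent value `z = cluster_shift + noise`. Metabolites map through a
log-normal link, `value = median · exp(σ_log · z)` (medians and log-SDs
in `METABOLITE_MARGINALS` are plausibility-based pediatric serum values
in μM; the study tables do not report per-metabotype metabolite
marginals, so these are not fitted quantities). Serum chemistry is
normal on the raw scale, `value = mean + sd · z`, truncated at
1 mg/dL. Log-normal metabolites guarantee positivity and reproduce the
right skew typical of μM panels.

**Covariance.** Within each metabolite block (11 amino acids; C0 plus
11 acylcarnitines) the noise is single-factor equicorrelated:
`noise = √ρ·f_block + √(1−ρ)·ε`, with ρ = 0.6 for amino acids and 0.45
for acylcarnitines. This makes the block PCAs strongly PC1-dominant
(amino-acid PC1 explains ~70% of block variance on default cohorts),
matching how such panels behave in practice. Chemistry residuals are
independent; the cluster shifts alone induce the glucose–lipid
correlation.

**Cluster shifts.** `LI` adds `lipid_shift_sd` (in within-cluster SD
units) to TAG, TC and glucose. `AA` adds `aa_shift_sd` to the nine
index amino acids plus citrulline and ornithine, and multiplies AC16 by
`betaox_suppression` (< 1), so the β-oxidation initiation proxy AC16/C0
is low in that group. Anthropometrics carry no cluster signal by
default (`aa_age_offset` can subtract years from the AA group's ages to
mimic the younger-children pattern seen in such cohorts; it defaults to
0).

**Calibration.** The default magnitudes — `lipid_shift_sd = 4.5`,
`aa_shift_sd = 4.5`, `betaox_suppression = 0.45`, `noise_sd = 1` — are
a documented constant chosen once so that the mean silhouette of the
3×1 SOM partition of the default n=658 cohort falls in the 0.30–0.40
band reported for healthy pediatric metabolomes (measured 0.33–0.35
across seeds). Large nominal shifts are needed because (a) the
feature matrix is z-scored on the mixture, which absorbs between-cluster
variance into the denominator, and (b) only ~3 of the 8 features are
informative for each cluster contrast while the block correlation
inflates within-cluster spread along exactly the informative
directions.

**Intervention kernel.** `apply_intervention` samples each child's
destination metabotype from a per-origin row of a transition matrix and
applies that transition's standardized shift vector (multiplicative on
the log scale for metabolites, additive in raw-SD units for chemistry).
The default kernel keeps about half of balanced children in place,
makes the lipid group the most stable, and migrates ~90% of the
amino-acid group, with shift vectors equal to the difference of the
destination and origin cluster-shift vectors (children move to the
destination profile in expectation).

**Metabolic-syndrome group.** `generate_mets_group` draws from the
balanced profile and then elevates TAG and glucose by `mets_shift_sd`
*pooled* SDs — pooled meaning the healthy cohort's marginal SD, which
includes the between-metabotype variance, measured from the healthy
marginal mean — lowers HDL (×0.8 of the shift), moderately raises TC
(×0.5; dyslipidemia travels with the syndrome), and elevates waist
circumference, blood-pressure percentiles and BMI z. Expressing the
shifts in marginal-SD units is what makes "2 SDs above the healthy
mean" hold exactly for the shifted chemistry and places the group on
the lipid-predominant profile rather than midway between clusters.

**What the generator does not emulate.** Real panels have heavier
tails, batch effects, detection limits, non-Gaussian block structure
and metabolite-specific biology; anthropometrics are only loosely
coupled to age/height and not to the metabolome. Passing tests on this
generator demonstrate that the pipeline recovers the structure it
assumes — not that real pediatric cohorts contain three clusters.

## 2. Normalization recipes

Each analysis variable gets one strictly monotone transform selected by
minimizing the Anderson–Darling normality statistic on the training
values, then standardized by its frozen post-transform mean/SD. The
default candidate set is parametric — identity, log, Box–Cox (MLE λ),
Yeo–Johnson — with the ordered-quantile map (Blom normal scores with
tie-averaged references, linear-tail interpolation on new data) held
back as a fallback for variables where no parametric candidate applies
(e.g. non-positive values with only log-family candidates available).

The rank map is deliberately excluded from the AD contest: it achieves
near-perfect normality for *any* input by construction, so letting it
compete makes "best transform" degenerate to marginal gaussianization —
which flattens multimodal marginals and thereby erases the
between-cluster signal the downstream clustering is meant to find
(empirically, it caps the achievable 3-cluster silhouette around 0.26
on this generator regardless of the true separation). Smooth parametric
transforms correct skew while preserving modes. Callers who want the
pure min-AD behaviour can pass `candidates=CANDIDATES, fallback=None`.

Recipes are serialized with all fitted parameters and reapplied
verbatim — row-wise independent, never refitted.

## 3. Indices and features

Block PCAs are eigendecompositions of the correlation matrix, with
eigenvector signs fixed (largest-magnitude element positive) and
components retained while eigenvalue > 1 (Kaiser); a near-unit
eigenvalue triggers an instability warning, and inputs whose
correlation matrix is undefined (constant columns) raise an error
naming the columns. Zero eigenvalues from collinear variables are
legal — they are simply never retained.

An index folds the retained components into a single per-variable
weight, `w_v = Σ_k loading_{v,k} · varfrac_k`, evaluated on member
variables standardized by frozen training means/SDs, with the overall
sign chosen so the index correlates positively with the mean of its
members. Defaults: AAI over Gly, Ala, Met, Val, Pro, Leu, Phe, Tyr,
Arg (Arg enters with its loadings on every retained component, which
includes the second component that it dominates); ACI over AC2, AC4,
AC8, AC10, AC16.

The SOM consumes exactly eight features in fixed order — glucose, TAG,
TC, C0, ACI, AAI, Cit, Orn — z-scored by frozen training parameters.
Without z-scoring the mg/dL chemistry would dominate the index scales.

## 4. The ring SOM

A 1×m toroidal grid is a ring; `ring_distance(i, j) =
min(|i−j|, m−|i−j|)`. Training is online: per presented sample the BMU
is the nearest codebook row, and all units update by the Gaussian
neighborhood rule. One iteration is a full pass over the data in a
freshly shuffled order; the default is 100 passes. α decays linearly
0.05 → 0.01 and σ from m/2 → 0.3 over all presentations. The final
radius matters: on a 3-ring every pair of units is at distance 1, and
σ_end = 0.5 leaves a neighbor update factor of exp(−2) ≈ 0.14 that
keeps dragging all codebooks toward the common mean, visibly degrading
cluster recovery; σ_end = 0.3 (factor ≈ 0.004) lets late training
behave like online k-means while the early wide-radius phase still
provides the topological ordering. Codebooks initialize from m distinct
training rows drawn under the config seed, so training is deterministic
given (data, config). BMU ties break to the lowest unit index.

`select_grid` trains one SOM per ring length 3–6 under the same seed
and schedule, scores each partition by mean silhouette (Euclidean), and
returns the argmax; candidates that leave a unit empty are ineligible.
Rows are put in canonical lexicographic order before training so the
selection is invariant to input row order.

**Naming** reads the characterization table, not unit order: METLI is
the unit maximizing mean standardized (glucose + TAG + TC)/3, METAA the
remaining unit maximizing mean AAI, METBA the rest. For m ≠ 3 units are
named `unit_0..unit_{m−1}`.

## 5. Internal validation

*Bootstrap stability*: B = 50 resamples of children with replacement;
the SOM is retrained on each resample (fresh seed spawned from the
master seed) and **all original children** are reassigned; the ARI
against the reference partition is recorded. The normalization recipe
and indices stay frozen — the resampling exercises the partition, not
the feature construction. Degenerate retrains (fewer than two occupied
units) are recorded as missing and excluded from the mean.

A caution on interpretation: stability indices of this kind have a
positive bias under the no-structure null. Bootstrap resamples share
about 63% of the children with the original sample, and any two
spatially contiguous partitions of the same point cloud agree well
above label-permutation chance; residual correlation structure (the
block factors) adds a reproducible continuum axis even when no clusters
exist. On zero-separation synthetic cohorts the mean bootstrap ARI sits
around 0.2–0.5 rather than 0. This is why the package always reports
the silhouette alongside the ARI: a stable partition of a continuum has
high ARI but near-zero silhouette, and only the combination supports a
cluster claim.

*Separability*: a Random Forest (500 trees, √p features per split, no
depth limit) predicts the SOM labels from the same eight features;
observed accuracy is the overall proportion correct on the held-out 20%
of a stratified 80/20 split. The null retrains on globally permuted
labels, re-splitting each time (more conservative than a fixed split),
n_perm = 250 by default; `p = (1 + #{null ≥ observed}) / (n_perm + 1)`.
Accuracy is unbalanced overall accuracy; stratification preserves class
proportions.

## 6. Frozen-model application

A `ModelBundle` (recipe + index definitions + feature scaling +
codebook + unit naming + seed) serializes to a single JSON file stamped
with a content-derived run ID; loading verifies the hash, so mixing
artifacts from different training runs, or editing a bundle by hand,
fails loudly. Classification is strictly: frozen recipe → frozen
indices → frozen scaling → BMU assignment → frozen naming.

Transition tables cross-tabulate paired pre/post labels (children
paired by ID; unpaired children excluded with a warning), report row
percentages, the overall percent reclassified, per-transition mean
metabolite deltas (post − pre), and the McNemar–Bowker symmetry test
`χ² = Σ_{i<j} (n_ij − n_ji)²/(n_ij + n_ji)` with df = k(k−1)/2, where
empty off-diagonal pairs are skipped with df reduced accordingly.

Group comparisons pick the omnibus test from the assumptions:
Anderson–Darling normality per group (5% level) and Levene's test
(median-centred) select ANOVA (+Tukey), Welch's ANOVA (+Games–Howell)
or Kruskal–Wallis (+Dunn with Bonferroni; the Dunn z-tests use the
tie-corrected rank variance). Omnibus p-values are Bonferroni-corrected
across the variable list of the report. Covariate-adjusted contrasts
come from per-variable OLS with metabotype indicators plus age, sex,
BMI z-score and waist circumference.

## 7. Numerical details and degenerate inputs

- Friedewald LDL is returned as missing (NaN) for TAG ≥ 400 mg/dL, the
  formula's validity bound, rather than raising.
- Robust z uses median and 1.4826·MAD; zero-MAD columns are skipped with
  a warning. The outlier screen removes whole children (any metabolite
  |z| > 5), deterministically.
- The metabolic-syndrome screen requires ≥3 of: TAG ≥ 110 mg/dL,
  HDL ≤ 40 mg/dL, glucose ≥ 110 mg/dL, SBP or DBP percentile ≥ 90, waist
  at or above the within-cohort 90th percentile (the schema carries
  waist in cm, not as a reference percentile; the cutoffs live in
  `CookConfig` and are editable).
- Filtering order is fixed: completeness → metabolic-syndrome screen →
  fasting (glucose ≥ 100 mg/dL) → metabolite outliers; the exclusion
  report accounts for every row.
- Cohort CSVs are written at 17 significant digits and read with
  round-trip float parsing, so write∘read is the identity.

## 8. Problem sizes

The shipped verification script (`scripts/acceptance.py`) uses the
study-scale sizes as the package's standard benchmark: n = 658 for
discovery, B = 50 bootstrap resamples, 250 label permutations on a
balanced n = 600 cohort, and an n = 203 metabolic-syndrome group. The
pytest suite exercises the same checks with the permutation count
reduced to 100 (identical pass criteria).

## 9. Known limitations

- The generator's marginals are plausibility-based, not fitted to any
  real cohort; absolute concentrations should not be quoted.
- The zero-separation negative control cannot drive the bootstrap ARI
  to zero for the structural reasons in section 5; silhouette is the reliable
  null diagnostic.
- Batch-SOM, 2-D grids and hexagonal topologies are out of scope, as
  are alternative stability indices (Jaccard, prediction strength) and
  Random-Forest hyperparameter tuning.
- BMI z-scores and blood-pressure percentiles are accepted as
  precomputed inputs; reference-table lookups are not implemented.
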