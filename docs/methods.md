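# Methods

This note documents the models, parameter choices, and numerical decisions
behind `metacoex`, and what the synthetic-data tests do and do not
demonstrate about real cohorts.

## Study design the package assumes

A single-arm treatment cohort measured on a targeted metabolomics panel at
two timepoints (baseline and week 12), with depression severity rated by
HAM-D17 at baseline, week 10, and week 12. Outcomes follow the standard
trial definitions: a **remitter** scores ≤7 at *both* week 10 and week 12
(this rule takes precedence); otherwise percent reduction from baseline to
week 12 classifies the subject as **responder** (≥50%), **partial
responder** (30–49%, inclusive at 30%), or **treatment failure** (<30%,
including worsening). Baseline eligibility requires HAM-D17 ≥ 15.

## Preprocessing

- **LOD filter** — a metabolite is excluded iff *strictly more than* 40% of
  its cohort (non-QC) measurements fall below the limit of detection. QC
  aliquots are instrument controls and never count toward the fraction.
- **Batch correction** — plates are rescaled per metabolite by
  `global QC mean / plate QC mean`, the global mean being the unweighted
  mean over all QC-pool measurements of that metabolite. All values on the
  plate (cohort and QC) are multiplied by the factor, which makes the
  operation idempotent; the plate's LOD entries are rescaled by the same
  factor so the subsequent LOD/2 imputation stays in corrected units.
- **Imputation and transform** — censored entries become LOD/2 (the
  plate-specific LOD when the table provides one), then everything is
  log2-transformed. Nonpositive values at this point are an error, not a
  silent fix.
- **Outlier flagging** — with more metabolites than samples the sample
  covariance is singular, so the literal "Mahalanobis distance with df =
  number of metabolites" recipe is undefined. Distances are therefore
  computed in the PCA subspace capturing ≥90% of variance, capped at n−2
  components; df equals the retained dimension, and the threshold is the
  chi-square quantile at `1 − 0.05/n`. The subspace and df used are recorded
  in the QC report. Samples are *flagged*, never silently removed
  (`drop_outliers` defaults to off). Distances are computed on the full
  two-timepoint log2 matrix.
- **Change scores** — `Δ = log2(week12) − log2(baseline)` per subject;
  subjects missing a timepoint are dropped with a logged warning.

## Network stage

- **Signed adjacency** `a_ij = ((1 + r_ij)/2)^β` maps correlation −1 → 0 and
  +1 → 1, so anticorrelated metabolites are unconnected. Default β = 18, a
  typical signed-network choice; `pick_soft_threshold` implements the
  scale-free topology criterion (equal-occupancy binning of connectivity,
  log-log regression of frequency density on mean connectivity, fit index
  negated for positive slopes, smallest β with fit ≥ 0.8, falling back to 18
  with a warning).
- **TOM** uses the standard overlap formula applied to the signed adjacency
  (the adjacency already encodes sign). The vectorized implementation is
  tested entrywise against a triple-loop oracle at 1e−12.
- **Dynamic hybrid tree cut** is reimplemented in its core two-stage form:
  average-linkage dendrogram on `1 − TOM`; a cut at a deep-split-dependent
  fraction of the joining-height range (deep split 0–4 maps to 0.95, 0.90,
  0.85, 0.80, 0.75 — higher deep split cuts lower and splits more
  aggressively); flat clusters with ≥ `min_size` leaves become cores; each
  remaining leaf joins the core with the smallest mean dissimilarity if that
  distance stays below the cut height, else it is left unassigned (grey).
  The reference algorithm's additional options (core scatter control,
  cluster trimming, external-branch switches) are deliberately out of scope.
- **Eigenvectors** — member change vectors are column-standardized (sample
  sd); the module eigenvector is the first left singular vector across
  subjects, unit norm, sign-fixed to correlate nonnegatively with the
  module's mean standardized profile so that module–trait signs are
  reproducible. Explained variance is `s₁²/Σs²`.
- **Merging** is greedy closest-pair: while any pair of module eigenvectors
  correlates above 0.75, merge the most-correlated pair and recompute. This
  satisfies the same terminal invariant as eigenvector-tree merging (no
  final pair above threshold) and its stepwise trace is tested against an
  independently scripted oracle.
- **Hubs** — per module, the member with maximal intramodular connectivity
  `kWithin_i = Σ_{j∈module, j≠i} a_ij`; ties break to the lexicographically
  smaller metabolite ID. Colors follow the conventional size-ordered color
  list with grey reserved for unassigned metabolites.

## Association stage

- Module- and metabolite-level associations are Pearson correlations with
  ΔHAM-D17 (raw change, week 12 − baseline), with two-sided p from
  `t = r√((n−2)/(1−r²))` on n−2 df. A module is flagged when |r| > 0.3 *and*
  p < 0.1 — the pilot-scale convention. At n = 26 the p < 0.1 bound
  corresponds to |r| > 0.33, so the p-criterion is the binding one and the
  null flag rate is 0.10 by construction; at larger n the |r| > 0.3 gate
  dominates.
- The covariate-adjusted model is **fixed-effects OLS**
  `Δmetabolite = b₀ + b₁·ΔHAMD + b₂·age + b₃·sex` (female = 0, male = 1).
  With exactly one change score per subject a per-subject random intercept
  is not identifiable, so a mixed model would degenerate to this OLS; the
  package states that substitution openly. Reported: b₁, a
  normal-approximation 95% CI (±1.96·SE), the two-sided t p-value, and
  Benjamini–Hochberg q-values across all metabolites. The design matrix is
  shared, so all metabolites are fit in one closed-form pass; a test
  cross-checks against statsmodels OLS.
- Trajectory contrasts use only the extreme outcome groups (remitters vs
  treatment failures), reporting mean ± SEM (sd/√n, sample sd) per
  metabolite, group, and timepoint, and a two-sided Welch t-test on baseline
  levels.

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 26 subjects, 180
metabolites on 3 plates with 2 QC aliquots each, eight planted modules of
sizes 8/15/12/96/5/6/3/9 (26 background metabolites), outcome mix
12/3/4/7, baseline HAM-D ~ N(18.6, 3.1) clipped to ≥15, ages uniform 18–65,
sex Bernoulli(0.615 female), within-module loading 0.85, residual sd 0.3,
three of the eight modules coupled to the trait at ρ = +0.36, −0.33, −0.31.

- **Change model** — per-module latent factor `f_m ~ N(0,1)` per subject;
  member change = `loading·f_m + noise_sd·ε`; background metabolites are
  pure noise with matched marginal variance. This is the simplest model
  producing the correlation structure a weighted co-expression analysis
  assumes.
- **Trait coupling** — latent trait `t = Σ ρ_m f_m + √(1−Σρ²)·ε` gives
  `corr(t, f_m) = ρ_m` exactly; the integer ΔHAM-D values from the
  trajectory simulator are then assigned to subjects comonotonically with
  `t`. For monotone couplings of normals the realized correlation is
  `ρ_m · corr(t, g(t))` with `corr(t, g(t)) ≈ 0.97–0.99` here, i.e. an
  attenuation below ~3%.
- **Trajectories** — each outcome category's triple is drawn inside its
  defining band, so the classifier round-trips every generated subject by
  construction; category counts come from largest-remainder apportionment
  of the configured proportions.
- **Measurement model** — two-timepoint log2 levels are reconstructed
  around metabolite-specific lognormal baselines (log2 mean ~ N(5, 1.5),
  between-subject sd 0.5); plate multipliers (defaults 1.0/1.15/0.9) scale
  measured values; QC aliquots share the pooled mean composition of all
  subject samples with optional log2-scale measurement noise
  (`measurement_noise_sd`, default 0); per-metabolite LODs sit at the
  `lod_quantile` (default 0.05) quantile of the measured values, and
  measurements strictly below are censored to NaN.

**What the generator does not emulate:** instrument drift within plates,
metabolite-class-specific noise, missingness beyond left-censoring,
correlated covariates (age/sex are independent of the metabolome), and any
real biochemical pathway structure. Passing the planted-recovery tests
therefore shows the pipeline is *algorithmically* correct and well
calibrated under its own assumptions — not that real cohorts of 26 subjects
yield stable modules. Cohort-scale sensitivity is the reason the reference
analysis is a pilot.

## Problem sizes used in the test and acceptance runs

Recovery checks use 8 planted modules (sizes 8/15/12/20/5/6/3/9, loading
0.85, noise 0.3) at n = 100 subjects over 20 seeds; calibration checks use
8 null modules per seed at the cohort size n = 26 over 100 seeds (800
draws) and a planted |ρ| = 0.5 module at n = 100 over 100 seeds; oracle
equivalences use 100 random 6-node networks (TOM) and 1000 random p-vectors
(BH). These sizes make the full suite run in well under a minute while
keeping every Monte-Carlo band statistically meaningful.

## Known limitations

- The dynamic hybrid cut is a core-form reimplementation; partitions can
  differ from the reference implementation on dendrograms with weak or
  nested structure.
- The greedy merge order can differ from eigenvector-tree merging when
  three or more modules are mutually near the threshold; the terminal
  invariant is the same.
- The scale-free fit uses equal-occupancy bins with a density estimate;
  fit indices are comparable within this package, not numerically
  interchangeable with other tools' fit tables.
- With m ≫ n the Mahalanobis flagging is conservative (empirical distances
  are bounded above), which is the safe direction for a QC screen.
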