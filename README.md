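# metacoex

Metabolite co-expression network analysis of treatment-response cohorts.

`metacoex` is built for the common design in clinical metabolomics where a
small cohort is profiled on a targeted panel (~180 metabolites, plate-based
LC-MS assays with pooled-QC aliquots) before and after a treatment course,
and the question is which *groups* of co-changing metabolites track the
change in a clinical severity score. The reference use case is a
cognitive-behavioral-therapy (CBT) depression cohort: plasma metabolites at
baseline and week 12, depression severity measured with the 17-item Hamilton
Depression Rating Scale (HAM-D17), and outcomes classified as remitter /
non-remitting responder / partial responder / treatment failure.

Because cohorts like this are rarely deposited, the package ships a
first-class synthetic-cohort generator with planted module structure, batch
effects, LOD censoring, and trait coupling, so every pipeline stage is
testable against known ground truth.

## What it computes

1. **Preprocessing** (`metacoex.preprocess`): exclude metabolites with >40%
   of cohort measurements below the limit of detection (LOD); remove
   between-plate batch effects with per-metabolite factors
   `global QC mean / plate QC mean`; impute remaining censored values at
   LOD/2; log2-transform; flag multivariate outlier samples by squared
   Mahalanobis distance against a Bonferroni-corrected chi-square threshold
   (`0.05/n`); form per-subject change scores
   `Δ_ij = log2 x_ij(week12) − log2 x_ij(baseline)`.
2. **Network** (`metacoex.network`): signed weighted adjacency
   `a_ij = ((1 + r_ij)/2)^β` (default β = 18, or chosen by the scale-free
   topology criterion), topological overlap measure

   `TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)`,

   average-linkage clustering of `1 − TOM` with a dynamic hybrid tree cut
   (deep split 2, minimum module size 3), module eigenvectors (first
   principal component of the standardized member changes across subjects),
   greedy merging of modules whose eigenvectors correlate above 0.75,
   conventional color names, and per-module hub metabolites (maximal
   intramodular connectivity `kWithin`).
3. **Association** (`metacoex.associate`): Pearson correlation of each
   module eigenvector and each metabolite with ΔHAM-D17; a module is called
   significant when |r| > 0.3 at uncorrected p < 0.1 (pilot-study
   convention); covariate-adjusted per-metabolite OLS
   (`Δmetabolite ~ ΔHAMD + age + sex`) with Benjamini–Hochberg q-values;
   remitter-vs-failure mean ± SEM trajectories with Welch baseline
   contrasts; a Table-1-style cohort summary.

## Worked example

```python
from metacoex import PipelineConfig, run_pipeline

manifest = run_pipeline(PipelineConfig(out_dir="run1", seed=1))
print(manifest["stages"]["network"])
```

prints (seed 1, default 26-subject synthetic cohort):

```
{'beta': 18, 'n_modules': 8,
 'module_sizes': {'turquoise': 96, 'blue': 15, 'brown': 12, 'yellow': 9,
                  'green': 8, 'red': 6, 'black': 5, 'pink': 3},
 'n_grey': 26, 'planted_ari': 1.0}
```

The generator plants eight modules of sizes 96/15/12/9/8/6/5/3 among 180
metabolites plus 26 background metabolites; the pipeline recovers exactly
that partition (adjusted Rand index 1.0), with the 26 unassignable
background metabolites in the grey module. `run1/` then contains
`qc_report.json` (540 LOD/2 imputations, no exclusions, no outlier flags at
these settings), `change_matrix.csv` (26 × 180), `modules.csv`,
`eigenvectors.csv`, `module_trait.csv`, `univariate.csv`,
`trajectories.csv`, `cohort_summary.json`, a module-trait heatmap
(CSV + PNG), and `manifest.json`. The cohort summary reproduces the planted
outcome mix: 12 remitters (46.2%), 3 responders (11.5%), 4 partial
responders (15.4%), 7 treatment failures (26.9%).

At n = 26 the planted module-trait correlations (|ρ| 0.31–0.36) sit at the
edge of detectability, so whether a given seed flags them is essentially a
coin flip — exactly the pilot-scale behavior the |r| > 0.3, p < 0.1 rule
implies. At n = 100 a planted |ρ| = 0.5 module is flagged in ~99% of runs
(see the acceptance script).

The same stages are available from the shell:

```bash
metacoex simulate --seed 1 --out sim/
metacoex run-all --seed 1 --out run1/ \
    --measurements sim/measurements.csv --lod sim/lod.csv --metadata sim/metadata.csv
metacoex network --changes run1/change_matrix.csv --beta 18 --out net/
```

## Layout

- `src/metacoex/synth.py` — synthetic cohort generator (planted factor
  model, HAM-D trajectory simulation, plate measurement model)
- `src/metacoex/preprocess.py` — LOD filter, QC-pool batch correction,
  imputation, outlier flagging, change scores
- `src/metacoex/network.py` — signed adjacency, soft-threshold selection,
  TOM, dynamic hybrid tree cut, eigenvectors, merging, hubs, colors
- `src/metacoex/associate.py` — module/metabolite-trait association,
  adjusted models, outcome classifier, trajectories, cohort summary
- `src/metacoex/pipeline.py`, `src/metacoex/cli.py` — orchestration,
  manifest, I/O, `metacoex` console script
- `docs/methods.md` — modeling assumptions, parameter choices, limitations
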