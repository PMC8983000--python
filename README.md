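# methyldrift

Paired DNA-methylome drift analysis for tumor cohorts profiled on Illumina
methylation arrays (450K/EPIC-style β-values), with a built-in synthetic
cohort generator so every stage can be exercised and validated offline.

The scientific setting is a longitudinal design: each subject contributes a
primary sample and a follow-up (e.g. recurrence) sample. The package
quantifies how far each methylome has drifted between the two timepoints and
whether that drift is concentrated in particular genomic contexts or gene
sets, and relates treatment groups through survival and response summaries.

## What it computes

- **QC / preprocessing** — β = M/(M+U+100) from raw intensities; probes with
  detection p > 0.05 are flagged, probes flagged in > 5 % of samples are
  masked, samples with > 30 % flagged probes are dropped; bisulfite-conversion
  failures (control mean below the grand mean − 3 SD across samples) are
  removed; sex-chromosome, polymorphic and cross-reactive probes are excluded;
  multi-platform cohorts are harmonized to shared probes.
- **Genomic context** — every CpG is assigned to exactly one of Island,
  Shore (≤ 2,000 bp from an island), Shelf (2,001–4,000 bp) or OpenSea.
- **Paired differential methylation** — per-CpG random-intercept linear mixed
  model (REML, subject intercept) with a Wald t-test on the timepoint term;
  in the balanced no-covariate case this reduces exactly to the paired
  t-test. CpGs are classified hyper-/hypomethylated when |Δβ| > 0.2 and
  Benjamini–Hochberg q < 0.05.
- **Methylation dysregulation index (MDI)** — per pair,
  100 × mean |β_followup − β_primary| over jointly observed CpGs, overall and
  per context; groups are compared with an exact Mann–Whitney U test.
- **Gene-set enrichment** — hypergeometric test plus a probe-number
  bias-corrected p-value from the Wallenius noncentral hypergeometric
  distribution (genes carrying more probes are more likely to be hit).
- **Survival & response** — Kaplan–Meier estimates with Greenwood/log-log
  median confidence intervals, and integer response-rate arithmetic.
- **Synthetic cohorts** — a seeded generator that injects a known drift
  fraction and effect size into a paired cohort (intensities, detection
  p-values, sample sheet, slides, FFPE noise, conversion failures) together
  with the ground truth, so recovery can be checked exactly.

## Quick start

Write a run config and let the pipeline simulate, QC and analyse a cohort:

```yaml
# example.yaml
seed: 7
simulate:
  n_cpgs: 2000
  n_subjects_per_group: 6
  drift_fraction: 0.05
  drift_effect: 0.3
  noise_sd: 0.05
classification_mode: fdr_and_delta
covariates: []          # paired design; subject-constant covariates are redundant
manifest_args:
  n_islands: 20
survival:
  groups:
    treated: {n: 14, median_days: 285.0, censor_rate: 0.1}
    control: {n: 14, median_days: 220.0, censor_rate: 0.1}
```

```bash
methyldrift run --config example.yaml --outdir run1
```

This writes `beta_clean.tsv`, `context_assignments.tsv`, `cpg_results.tsv`,
`mdi.tsv`, `enrichment.tsv`, `survival.csv`, `qc_report.json`, the resolved
config and a deterministic `summary.json`. With the config above the summary
contains (actual output):

```json
"differential": {"n_hyper": 55, "n_hypo": 45, "n_unchanged": 1889},
"ground_truth": {"n_injected": 100, "n_recovered": 100,
                 "precision": 1.0, "recall": 1.0},
"mdi": {"per_group_mean": {"control": 4.189, "treated": 5.091},
        "comparison": {"p_value": 0.00216, "method": "exact_enumeration"}},
"qc": {"n_retained_probes": 1989, "n_retained_samples": 24}
```

All 100 injected drifted CpGs (5 % of 2,000 at |Δβ| = 0.3) are recovered
with no false positives, and the treated group's MDI separates from the
control group's technical-noise floor.

Each stage is also exposed individually (`methyldrift simulate`, `qc`,
`context`, `diff`, `mdi`, `enrich`, `survival`); run any of them with
`--help` for the file interfaces. Identical config + seed yields a
byte-identical `summary.json`. Exit codes for `methyldrift run`: 0 success,
2 config validation error, 1 stage failure.

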