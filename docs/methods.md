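# Methods

This note documents the statistical model, the defaults, and the numerical
design decisions behind `methyldrift`.

## 1. β-values and QC

β-values are computed from methylated (M) and unmethylated (U) channel
intensities as

    β = M / (M + U + 100)

with the conventional offset of 100 stabilising low-intensity probes; β is
therefore always in [0, 1). Negative intensities are rejected.

QC applies, in order, with **strict** inequalities throughout:

1. **Platform harmonization** — when a cohort mixes array platforms, only
   probes present on every platform are retained.
2. **Bisulfite-conversion controls** — per-sample means of the conversion
   control probes are compared to the cohort grand mean; a sample is dropped
   when its mean is strictly below `grand_mean − 3·SD`, where the SD is taken
   across per-sample means with `ddof=1`. With a single outlier among n
   samples the largest standardised deviation is (n−1)/√n, so the rule can
   only ever fire for n ≥ 12; small cohorts pass this filter by
   construction. A matrix with zero control probes is an explicit error
   rather than a silent skip.
3. **Detection flags** — entry flagged when detection p > 0.05; a sample is
   dropped when > 30 % of its probes are flagged; probe masking (flagged in
   > 5 % of samples) is then recomputed on the surviving samples.
4. **Annotation exclusions** — X/Y-chromosome, polymorphic and
   cross-reactive probes, and the control probes themselves, are removed.

Masked and retained probes always partition the manifest; flagged entries on
surviving probes are set to missing rather than imputed.

## 2. Genomic context

Islands are read from BED (0-based half-open) and converted to 1-based
inclusive coordinates; overlapping or adjacent islands are merged with a
warning. For a CpG at distance d from the nearest island on its chromosome:

| context | rule |
|---|---|
| Island  | inside an island (d = 0) |
| Shore   | 0 < d ≤ 2,000 bp |
| Shelf   | 2,000 < d ≤ 4,000 bp |
| OpenSea | d > 4,000 bp, or no island on the chromosome |

Boundaries are inclusive on the near side: d = 2,000 is Shore, d = 4,000 is
Shelf. Every analysis CpG receives exactly one context.

## 3. Paired differential methylation

Per CpG, the model is a random-intercept linear mixed model

    β_ij = x_ij'γ + u_i + ε_ij,  u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_e²)

fit by REML with a 1-D profile over λ = σ_u²/σ_e². For the block-diagonal
subject structure, (I + λJ)⁻¹ = I − λ/(1 + λn_i) J gives closed-form GLS
pieces, so the profiled −2·REML log-likelihood is scalar-minimised over
log λ (bounded, `xatol = 1e-12`), with the boundary λ = 0 compared
explicitly. Inference on the timepoint coefficient uses a Wald t with
containment degrees of freedom, df = N − rank(X) − (g − 1) for g subjects.

In the balanced paired case with no covariates this is *exactly* the paired
t-test (df = n − 1), which is the oracle used in the tests: agreement with
`scipy.stats.ttest_rel` is within 1e-6 in p on 100 random fixtures, and the
coefficient/SE match `statsmodels` `MixedLM`. Aliased design columns are
dropped deterministically left-to-right (intercept and timepoint are always
kept first).

A CpG is called hypermethylated when Δβ > 0.2 (mean over complete pairs) and
BH q < 0.05, hypomethylated for Δβ < −0.2; a `delta_only` mode classifies on
the effect size alone. Both thresholds are strict. BH q-values come from
`statsmodels` with NaN passthrough; the test suite cross-checks a
brute-force step-up implementation.

**Covariates and small cohorts.** The default model includes age, sex,
preparation (frozen/FFPE) and slide. In a fully paired cohort these are
subject-constant, hence absorbed by the subject intercept and uninformative
for the timepoint effect, while still consuming containment df: with 6 pairs
the full covariate set leaves df ≈ 2 and destroys FDR power. Recovery
analyses therefore use the timepoint-only model (`covariates: []`), which is
statistically equivalent for the within-subject contrast; the covariate
machinery matters for unbalanced or partially paired designs.

## 4. Methylation dysregulation index

For one pair,

    MDI = 100 × Σ_j |β_followup,j − β_primary,j| / N

with N the number of jointly non-missing CpGs. Context-stratified MDIs use
the same formula within each context; the global MDI is exactly their
count-weighted mean (tested to 1e-12). On a noise-free synthetic cohort with
drift fraction f and effect size |d|, MDI = 100·f·d identically.

Group comparisons use the Mann–Whitney U test: full enumeration of all
label assignments (midranks for ties) when the combined n ≤ 12 — two-sided
p = min(1, 2·min(P(U ≤ u), P(U ≥ u))) — and scipy's tie-corrected normal
approximation otherwise; the method used is reported alongside the p-value.

## 5. Gene-set enrichment with probe-number bias correction

A gene is significant when ≥ 1 of its surviving probes is significant, so
genes with more probes are hit more often by chance. Alongside the central
hypergeometric upper tail, a bias-corrected p-value is computed from the
Wallenius noncentral hypergeometric distribution
(`scipy.stats.nchypergeom_wallenius`), collapsing per-gene probe-count
weights (normalised to mean 1) to two colors: odds = mean weight inside the
set / mean weight outside. With equal weights this reduces to the central
hypergeometric (tested to 1e-6); the tail is validated against a
Monte-Carlo weighted-urn simulation within 3 standard errors. Probes
annotated to several genes count once per gene. Set-level q-values are BH
over the bias-corrected p-values.

## 6. Survival and response

Kaplan–Meier curves use lifelines (product-limit estimator, Greenwood
variance, log-log confidence bands); the median CI is read off the band
crossings, with unreached limits rendered as "NR". Ties between events and
censorings at a time follow the events-first convention. With no censoring,
S(t) equals the empirical fraction of times > t exactly. Response rates are
100·count/n rounded half-up to integer percent; counts must sum to n.

## 7. Synthetic cohort generator

The generator produces a manifest (4 autosome-like chromosomes plus X,
islands spaced 60 kb apart, genes as 50-kb windows, bisulfite control
probes), then a paired cohort:

- Baseline β per CpG from context-specific Beta distributions:
  Island Beta(1.5, 8), Shore Beta(2, 4), Shelf Beta(4, 3), OpenSea
  Beta(6, 2.5) — unmethylated islands, mostly methylated open sea.
- Drift: exactly `round(drift_fraction × n_cpgs)` analyzable CpGs receive a
  ±`drift_effect` shift at follow-up in the treated group only
  (`drift_direction_mix` sets the hypo fraction); baselines are adjusted so
  the shifted value stays within [0.001, 0.99].
- Noise on the logit scale with SD `noise_sd / 0.25` (so a perturbation of
  `noise_sd` at β = 0.5 has the nominal size), multiplied by 1.5 for FFPE
  samples; per-slide intercepts with SD `slide_effect_sd`; both members of a
  pair share a slide so slide effects cancel within pairs.
- Intensities: M = β·10,000 with M + U = 9,900, inverting exactly through
  β = M/(M+U+100); β is clamped to ≤ 0.99, the maximum representable at
  this fixed total intensity.
- Detection failures at rate `detection_fail_rate` (p ~ U(0.06, 0.8),
  passes ~ U(5e-4, 0.01)); optional injected conversion-failure samples.
- Survival times are exponential with the requested median; censoring is an
  independent exponential with rate chosen so the expected censored fraction
  equals `censor_rate`.

Everything is driven by `numpy.random.default_rng(seed)`; identical seeds
give identical cohorts, and ground truth (drifted CpGs, directions, expected
noise-free MDI) is emitted alongside.

**Scope/limits.** The generator models drift, batch, preparation and
detection artifacts — not cell-type composition, copy-number interference,
probe cross-hybridisation structure, or realistic genome coordinates; it is
a test harness for the statistics, not a biological simulator.

## 8. Determinism and numerics

- `summary.json` contains no timestamps, keys are sorted, and non-finite
  floats are serialised as strings, so identical config + seed ⇒
  byte-identical output.
- Thresholds live in one place (`pipeline.DEFAULT_THRESHOLDS`) and are
  validated to [0, 1] before any stage runs; the resolved config (with a
  SHA-256-derived hash) is written back out with every run.
- Exact enumeration paths (Mann–Whitney, hypergeometric tails) are preferred
  at small n; asymptotic approximations are used only beyond documented
  cutoffs and the choice is reported in the output.
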