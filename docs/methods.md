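# Methods

## The causal model and its assumptions

`grsmr` estimates the causal effect of ln 25-hydroxyvitamin D on ln thyroid
peroxidase antibody concentration (and the reverse) with a single-instrument
allele-score design. Each weighted genetic risk score (GRS) is assumed to be

1. **relevant** — associated with its own phenotype (checked by the
   incremental-R² F-statistic),
2. **exchangeable** — independent of confounders of the phenotype pair
   (screened by regressing age, BMI, waist-to-hip ratio and sex on each SNP
   and each GRS), and
3. **exclusion-restricted** — affecting the outcome only through the
   exposure (probed by per-SNP outcome associations; a pleiotropic path can
   be simulated with `beta_grs_outcome_direct` to see its bias).

Under these assumptions the Wald ratio β_out/β_exp of the two reduced-form
coefficients identifies the causal effect. For one instrument it coincides
exactly with two-stage least squares; the test suite asserts this to 1e-6
against an independent just-identified IV solve.

### Interval estimation

The SE comes from the first-order delta method,
SE_IV = |β_IV|·sqrt((SE_exp/β_exp)² + (SE_out/β_out)²), and the interval is
the symmetric normal β_IV ± 1.96·SE_IV. This is a deliberate fidelity choice:
no Fieller or bootstrap interval is offered, although the symmetric interval
is known to undercover when the first stage is weak (the ratio's distribution
is then heavy-tailed and skewed). The weak-instrument flag (F < 10) surfaces
exactly the regime where this caveat bites. When β_out = 0 the general
formula is an indeterminate 0·∞; the limit form SE_IV = |SE_out/β_exp| is
used. A first-stage coefficient below 1e-10 in magnitude is treated as a null
instrument (error) rather than allowed to produce an astronomical ratio.

### Component regressions

Both component fits use the same model-2 covariates (age, sex, waist-to-hip
ratio) in ordinary least squares with classical (non-robust) standard errors
and listwise deletion — matching common statistical-package defaults for this
kind of analysis. All confidence intervals use the fixed multiplier 1.96
rather than t-quantiles; at the sample sizes involved the difference is
negligible, and it keeps the delta-method interval self-consistent. The
instrument-strength R² is the *incremental* R² of the GRS over the
covariates (full-model R² minus covariate-only R²), an assumption made
because a GRS-specific R² is what the F approximation F = R²(n−2)/(1−R²)
expects.

## Genetics

Dosages are additive (0/1/2 copies of the effect allele). The GRS is the raw
weighted sum Σ w·dosage — not standardized, so tertile cutpoints are on the
natural weighted-sum scale. Individuals missing ≤ 2 of the 8 panel genotypes
have those dosages mean-imputed as 2·EAF from the panel file (the common
allele-score convention, preserving n); individuals missing more are excluded
by the filter, which removes in order (1) > 2 missing genotypes, (2) missing
TPOAb, (3) missing 25(OH)D, and reports each stage's count. Hardy-Weinberg
equilibrium is tested with the 1-df Pearson chi-square against p̂²/2p̂q̂/q̂²
expectations (the form whose statistic is conventionally reported as χ²);
monomorphic sites return χ² = 0 with a degenerate flag rather than an error.
VCF ingestion uses GT hard calls only: phased separators are accepted, any
missing allele makes the call missing, and an allele other than REF/ALT
(effect) yields a missing dosage — no strand flipping or allele harmonisation
is attempted beyond effect-allele matching.

## The synthetic cohort generator

The generator emulates the cohort the analysis was designed for, so that the
pipeline is testable without private data. What it reproduces:

- genotypes drawn as Binomial(2, EAF) per SNP — HWE by construction, no
  linkage disequilibrium (the real panel was selected for r² = 0), at the
  published EAFs;
- phenotypes generated on the ln scale by a recursive structural model and
  exponentiated (both phenotypes are log-transformed before analysis, so the
  log-linear form is the natural generative model). Genetic and covariate
  terms are centred, so the marginal locations stay at the configured
  intercepts whatever the effect sizes;
- covariate margins: age 55 ± 13 y, 40% male, WHR 0.86 ± 0.08,
  BMI 24.6 ± 3.6 kg/m² — the reported demographics of the emulated cohort;
- cell-wise genotype and phenotype missingness, with the mask returned so
  exclusion accounting can be verified exactly.

Default effect sizes are the reported first-stage coefficients
(β(VD_GRS→ln25OHD) = −0.093, β(TPOAb_GRS→lnTPOAb) = 0.345 per GRS unit) and a
true causal effect of −0.72 (the reported forward IV estimate); the reverse
causal effect defaults to 0 (the reported null). Residual SDs (0.30 for
ln 25(OH)D, 1.40 for ln TPOAb) are calibrated to the reported natural-scale
dispersions (≈ 41 ± 13 nmol/L and ≈ 114 ± 300 U/ml): for a log-normal,
σ_ln² = ln(1 + (s/m)²) gives ≈ 0.31 and ≈ 1.44 respectively. The ln TPOAb
residual is only loosely identified by those margins; it is held fixed rather
than tuned. Intercepts 3.66 and 3.70 put the exponentiated medians at
≈ 39–40 units. Covariate effects on the ln-phenotypes are small, plausible
values (e.g. women slightly higher TPOAb, adiposity slightly lower vitamin D);
they exist so that adjustment does something, and their exact values are not
load-bearing for any test.

A latent standard-normal confounder can be loaded onto both phenotypes
(`confounding_exposure`, `confounding_outcome`, default 0) to reproduce the
design's motivating contrast: the observational regression is biased, the IV
estimate is not (demonstrated in the test suite).

What the generator does **not** emulate: linkage disequilibrium, population
stratification or relatedness, genotyping error, assay floor/ceiling effects,
the extreme right tail of antibody titres beyond log-normality, or
informative (non-random) missingness. Passing tests therefore show the
estimator is correct under its own assumptions — not that those assumptions
hold in any real cohort.

Randomness: one integer seed drives four named child streams (genotypes,
covariates, phenotypes, missingness) via `numpy` seed sequences, so any stage
re-run with the same config is bit-identical and the full pipeline is
deterministic given (seed, config).

## Regression and table conventions

Tertiles use the empirical 1/3 and 2/3 quantiles with ties at a cutpoint
assigned to the lower group; fewer than three distinct values is an error.
Across-tertile trend tests are one-way ANOVA (continuous) and Pearson
chi-square without continuity correction (categorical); the adjusted
P-for-trend enters the tertile index 1/2/3 as a linear ordinal term — one of
two defensible conventions (the other is group-median scoring), chosen and
documented here as an assumption. When a confounder is itself the modelled
outcome it is dropped from its own adjustment set, and BMI and WHR are never
co-adjusted. Sex is coded male = 1 and modelled by logistic regression with
results on the odds-ratio scale; the coding is documented and flippable by
recoding the column. Output tables round to 3 decimals; full precision is
kept internally.

## Problem sizes used by the checks

The replicate-based checks run at the generator's native scale: 100 seeded
replicates of n = 10000 for forward-interval coverage of the true effect
(expected ≈ 95%, asserted ≥ 90%), 500 replicates of n = 10000 for null
calibration (exclusion count asserted inside the binomial 99% interval around
5% of 500), 20 cohorts of n = 2000 for the 2SLS identity, and ≥ 100 random
small instances per statistic for the brute-force oracle suites. These sizes
were chosen to make the binomial assertions sharp while keeping the whole
suite around a minute of compute.

## Known limitations

- The symmetric delta-method interval is anti-conservative under weak
  instruments (flagged, not corrected).
- Single-instrument per direction: no IVW/MR-Egger/weighted-median
  multi-instrument estimators, hence no internal pleiotropy-robust
  sensitivity analysis beyond the confounder screen.
- The shipped panel weights are synthetic placeholders; real analyses must
  supply externally estimated weights, and all GRS-scale quantities
  (tertile cutpoints, per-unit coefficients) depend on them.
- Complete-case analysis throughout; missingness is assumed ignorable.
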