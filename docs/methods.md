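# Methods

## Genetic correction model

A biallelic SNP with effect-allele frequency `p` is assumed to act
multiplicatively on the biomarker: each allele copy scales the level by the
relative allelic effect `a`, estimated as `exp(slope)` from ordinary least
squares of the natural-log biomarker on allele count (0/1/2). Natural
logarithms are used throughout and the back-transform is a plain `exp`; no
smearing/retransformation factor is applied to `exp(slope)` — the estimand is
the multiplicative genotype contrast, for which the naive back-transform is
consistent.

Unnormalized genotype effects `(1, a, a²)` are divided by the population-mean
effect `E = w_OO + w_OX·a + w_XX·a²`. Two weight choices are supported:

* `hwe` (default for tabulated output): `w = ((1−p)², 2p(1−p), p²)` from the
  panel allele frequency;
* `empirical`: the observed genotype proportions of the analysed cohort.

Either way the normalized effects have weighted mean exactly 1, so the
combined factor `G_i = Π_s e_s(genotype_is)` hovers around 1 in the
population and `corrected_i = measured_i / G_i` stays on the measurement
scale. Under linkage equilibrium the mean of a product of independent mean-1
factors is ≈1 already, so no renormalization of the multi-SNP product is
performed (the property is asserted in tests instead of forced). A missing
genotype contributes a neutral factor 1 and a per-participant flag; the
participant is kept (`correction unavailable = no correction`) rather than
dropped, preserving cohort size. Effects are always expressed for the stated
effect allele; `a < 1` (a decreasing allele) is accepted as-is with no silent
re-orientation.

### The rounded published panel row

For the first default-panel SNP (p = 0.33, a = 1.08) the HWE normalization
gives `E = 1.053497` and genotype effects `(e_OO, e_OX, e_XX) =
(0.9492, 1.0252, 1.1072)`, i.e. `(0.95, 1.03, 1.11)` at two decimals. The
triple commonly tabulated for this SNP, `(0.95, 1.02, 1.10)`, is *not*
reproducible from the two-decimal inputs: it corresponds to an unrounded
allelic effect of ≈1.075, which itself prints as 1.08. The package therefore
reports what the formula yields from the inputs it is given and documents the
one-ulp discrepancy rather than special-casing the row. The second
default-panel SNP's commonly tabulated triple `(XX 0.92, OO 1.11, OX 1.00)`
is inconsistent with the multiplicative normalization for *any* orientation
of the effect allele at p = 0.47, a = 1.10 (a column swap is the likely
origin); it is never used as an oracle, and the package recomputes
`(0.91, 1.00, 1.10)` from the stated frequency and effect.

## Synthetic cohort generator

The generator reproduces the structure the analysis assumes, with defaults
set to the study conditions of the motivating cohort:

| parameter | default | meaning |
|---|---|---|
| `n_participants` | 9819 | cohort size |
| `snp_panel` | (rs12506899: p=0.33, a=1.08), (rs2251844: p=0.47, a=1.10) | generative truth |
| `afp_median` | 2.70 ng/mL | median of the genotype-free AFP component |
| `log_noise_sd` | 1.0 | SD of the natural-log AFP residual |
| `detection_limit` | 0.005 ng/mL | assay floor applied to observed AFP |
| `baseline_incidence` | 0.00581 | marginal probability of incident HCC |
| `true_or_per_10` | 5.0 | OR per 10 ng/mL of the genotype-free component |
| covariates | male 46.9%, smoking 30.3%, drinking 27.2%, married 89.9%, college 10.4%, active 88.5%, family history 3.0%; age 62.09±7.78 y, BMI 24.33±3.32 kg/m² | baseline marginals |

Genotypes are Binomial(2, p) per SNP (exact HWE, linkage equilibrium). AFP is
log-normal: `ln latent = ln(median) + ln G + ε` with the genetic term
centred by `c = Σ_s ln E_s` so that it equals the mean-1 normalized factor
and `afp_median` remains interpretable as the median of the genotype-free
component. The observed value is `max(latent, detection_limit)`. The log-AFP
residual SD is not an externally known quantity for this setting; 1.0 is a
realistic right-skew for a near-zero serum marker and is a free parameter of
the generator. The marginal AFP median/IQR of real cohorts is matched in
shape (right-skewed, median ≈ 2.7) but not digit-for-digit.

Outcomes are Bernoulli with `P = expit(α + ln(OR₁₀)·x/10 [+ covariate
offsets])` where `x` is the genotype-free component, and α is solved by
bisection so the simulated marginal incidence equals the target to < 1e-6.
Driving the outcome by the genotype-free component encodes the working
hypothesis under which correction can help: the heritable part of the
measurement is noise with respect to disease. Covariates are drawn
independently of genotype and (by default) of outcome — they exercise the
adjusted-model plumbing, not confounding; `covariate_log_odds` can add
per-covariate log-odds contributions, with α re-solved so the marginal stays
calibrated. Missing genotypes appear only when `genotype_missing_rate > 0`
(default 0).

What passing tests on these cohorts do **not** show about real data: no
linkage disequilibrium between panel SNPs, no population stratification or
genotyping error, no genotype–covariate or covariate–outcome confounding by
default, and a correctly specified logistic link — real-data gains from
correction may be smaller or larger than the simulated ones.

## Risk models

Unconditional logistic regression (maximum likelihood, Newton iterations to
gradient tolerance 1e-10, max 100 iterations, via statsmodels) of the binary
outcome on the biomarker scaled to per-10-ng/mL units, under three covariate
sets: model 1 univariate; model 2 adds age, sex, smoking, drinking; model 3
adds education, marriage, BMI, physical activity and family cancer history.
Sex and the lifestyle variables enter as 0/1 indicators; age and BMI are
continuous (the simplest faithful coding). Wald 95% CIs
`exp(β ± z₀.₉₇₅·SE)` and two-sided normal p-values are reported; the exact
quantile 1.95996 is used so CI and p agree. Complete-case rows are counted
per model and reported as `n_used`. Separation or non-convergence sets
`converged=False` (NaN interval) instead of failing silently. Subgroup
analyses stratify by sex, age (<62 / ≥62, boundary in the upper stratum),
BMI (<24 / ≥24), smoking and drinking, each adjusted for the full model-3
set minus the stratifying variable; strata below 50 participants or with a
single outcome class yield NA rows. No multiple-testing adjustment is applied
across models or subgroups. Logistic (not time-to-event) regression is the
deliberate model class for this design.

## Discrimination

The AUC is the midrank Mann–Whitney estimator (ties count ½), computed in
O(n log n); per-case and per-control placement values give its variance
`var(V10)/m + var(V01)/n` and, for two scores measured on the same
participants, the paired variance of the AUC difference through their
covariances. The paired z-test uses a two-sided normal p by default; a
participant-resampling bootstrap SE is available behind a flag for small
samples. Operating points maximize the Youden index `J = sens + spec − 1`
over observed score values (positive call at `score ≥ threshold`), breaking
ties toward the higher, more specific threshold. The relative AUC improvement
is reported as `100·(AUC_b − AUC_a)/AUC_a` (e.g. 0.611 → 0.726 gives
+18.8%), with the absolute difference in points reported alongside — the
relative reading is the only one consistent with that AUC pair being
described as an 18.8-point gain.

## Numerical and reporting choices

* Quantiles use linear interpolation between order statistics (numpy
  default, type 7); stated because IQRs are part of the descriptive output.
* All randomness flows from one `numpy.random.default_rng(seed)` passed down
  explicitly; identical config + seed gives byte-identical report TSVs.
* Genotype-effect internal-consistency invariants use tolerance 1e-12 for
  exactly constructed effects and 0.005 for effects read from two-decimal
  published values (one-ulp rounding of a ratio of two rounded values can
  still exceed this; such rows are rejected rather than silently accepted).
* The directional-improvement property uses allelic effects (1.6, 1.8) at
  n = 30 000 and incidence 0.006: with the realistic effects (1.08, 1.10) the
  genetic log-variance (≈0.005) is negligible against the log-noise variance
  (1.0), so no AUC change is detectable at cohort sizes a test suite can
  afford; the scaled effects make sd(ln G) ≈ 0.42, large enough for the
  paired test to have power while leaving the noise term dominant.
* Simulation-based checks in the test suite run at n between 20 000 and
  100 000 with 5–2000 replicates depending on the property; these sizes were
  chosen so that 3-standard-error acceptance bands are decisive.

## Known limitations

Single-SNP additive log-linear effects only (no dominance, epistasis or
haplotypes); no SNP discovery; the correction assumes the panel's allele
frequencies and effects are externally estimated and transportable to the
analysed cohort; Wald inference can be anticonservative with very few cases
(subgroup rows with tens of cases should be read with care).
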