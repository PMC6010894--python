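# gcorrect — genetic correction of serum tumor-biomarker levels

Serum alpha-fetoprotein (AFP) is the standard screening biomarker for primary
hepatocellular carcinoma (HCC), but part of its inter-individual variation is
heritable rather than disease-related: common SNPs shift a healthy person's
baseline AFP up or down. `gcorrect` implements the *genetic correction* of such
a biomarker and evaluates whether the corrected value predicts disease better
than the raw measurement. It is aimed at epidemiologists and biostatisticians
working with prospective cohorts that carry biomarker measurements, genotypes
and an incident binary outcome.

## The model

For each biomarker-associated SNP *s* with effect-allele frequency *p* and
relative allelic effect *a* (the multiplicative factor per allele,
`a = exp(slope)` from OLS of ln biomarker on allele count), the unnormalized
genotype effects are `(1, a, a²)` for non-carriers (OO), heterozygotes (OX)
and homozygous carriers (XX). They are normalized by the population-mean
effect under Hardy–Weinberg equilibrium,

    E = (1−p)² + 2p(1−p)·a + p²·a²,
    (e_OO, e_OX, e_XX) = (1/E, a/E, a²/E),

so the population mean of the genotype effect is exactly 1. An individual's
combined genetic factor is the product over the panel,
`G_i = Π_s e_s(genotype_is)`, and the corrected biomarker is

    corrected_i = measured_i / G_i .

Downstream, the package fits unconditional logistic models of incident
disease on the biomarker scaled to 10 ng/mL units (three nested covariate
sets, plus subgroup analyses), and compares the discrimination of raw vs
corrected biomarker with the paired nonparametric (DeLong-type,
placement-value) test of the AUC difference, reporting a Youden-index
operating point with sensitivity and specificity.

A synthetic-cohort generator (`gcorrect.simulate`) reproduces the assumed data
structure — HWE genotypes, log-normal AFP with multiplicative genotype
effects, an assay detection-limit floor at 0.005 ng/mL, a rare incident
outcome calibrated to a target marginal incidence, and baseline covariates at
configurable prevalences — so the whole pipeline is testable without access
to any cohort data.

## Worked example

Generate a cohort of 30 000 participants in which the two-SNP panel has
amplified allelic effects (1.6 and 1.8) so the benefit of correction is
visible at this sample size, then run the full pipeline:

```yaml
# analysis.yaml
simulation:
  n_participants: 30000
  baseline_incidence: 0.006
  snp_panel:
    - {snp_id: rs12506899, p: 0.33, a: 1.6}
    - {snp_id: rs2251844, p: 0.47, a: 1.8}
seed: 11
out_dir: out
```

```bash
gcorrect run --config analysis.yaml
# raw AUC 0.871 vs corrected AUC 0.874 (relative change 0.4%, p=0.00655)
```

The Markdown summary written to `out/summary.md` includes (abridged):

```
Cohort: n=30000, incident cases at 5.87/1000.

## Genetic correction
- mean AFP 4.480 -> 4.311 ng/mL (3.8% change)

## Risk models (OR per 10 ng/mL)
- afp_per10 model1 [adj: none]: 2.52 (2.34-2.73), p=3.21e-123
- corrected_afp_per10 model1 [adj: none]: 3.01 (2.76-3.29), p=4.12e-134

## Discrimination
- raw AFP AUC 0.871 (0.838-0.904), sens 74.4%, spec 88.2%
- corrected AFP AUC 0.874 (0.840-0.908), sens 74.4%, spec 89.4%
- paired AUC difference +0.003 (z=2.72, p=0.00655); relative change 0.4%
```

Reading these numbers: the outcome is generated from the genotype-free AFP
component only, so dividing out the genetic factor removes pure noise from
the exposure — the odds ratio per 10 ng/mL rises from 2.52 to 3.01, and the
paired placement-value test finds the corrected AUC significantly higher
(p = 0.007) even though the absolute AUC gain is small. With the realistic
allelic effects of the default panel (1.08 and 1.10) the genetic variance is
a tiny fraction of the total log-AFP variance, and a cohort of ~10 000 shows
no detectable AUC change — which is why the acceptance properties that probe
directionality use the amplified panel.

Each subcommand is also available separately:

```bash
gcorrect simulate --n 9819 --seed 11 --out cohort.tsv
gcorrect correct --cohort cohort.tsv --out corrected.tsv
gcorrect risk --cohort cohort.tsv --models 1,2,3 --subgroups --out risk.tsv
gcorrect discriminate --cohort cohort.tsv --out roc.tsv
```

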