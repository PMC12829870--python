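# g6pdhb

Does HbA1c detect abnormal glucose tolerance in people with G6PD deficiency?

G6PD deficiency — carried by ~1 in 10 sub-Saharan Africans via the X-linked
*G6PD* A- haplotype — shortens red-cell lifespan and depresses glycated
hemoglobin (HbA1c) by ~0.9% without changing glycemia. Screening with the
standard HbA1c ≥ 5.7% threshold can therefore miss prediabetes and type 2
diabetes entirely in deficient individuals: in the Africans in America cohort
the sensitivity of HbA1c against the OGTT reference was 0% (0/17) with
deficiency versus 50% (98/195) with normal enzyme activity.

This package implements that analysis end to end, for epidemiologists and
statistical geneticists working with similar cohorts:

* **`variants`** — sex-specific *G6PD* A- haplotype calling from risk-allele
  dosages at rs1050829/rs1050828/rs76723693/rs137852328 (hemizygous-male
  normalisation, heterozygous-male errors, completion-based missing-data
  policy), plus the rs1050828-only screen and its miss analysis.
* **`glycemia`** — OGTT classification (prediabetes: fasting ≥ 100 and/or 2h
  ≥ 140 mg/dL; T2D: ≥ 126 / ≥ 200) and HbA1c flags (≥ 5.7%, ≥ 6.5%), with
  exclusion handling.
* **`status`** — deficiency status from genotype and/or the enzymatic assay
  (the assay wins; heterozygous women without an assay are indeterminate),
  genotype–assay concordance, prevalence tables.
* **`diagnostics`** — stratified sensitivity/specificity with Wilson
  intervals, the mean-shift HbA1c re-evaluation, and the group-comparison
  test battery (Welch t, Mann–Whitney, chi-square, one-way ANOVA).
* **`simulate` / `cohort_io`** — a seeded synthetic cohort generator
  calibrated to the cohort's published structure, written/read as chrX VCF +
  phenotype TSV.
* **`pipeline`** — `run_pipeline` composing all stages into JSON/TSV reports.

The numbered scripts under `analysis/` run the study as a narrative:
simulate, call haplotypes, resolve status and concordance, evaluate HbA1c
diagnostics, assemble the full report (outputs under `results/`).

## Worked example

```python
from g6pdhb import (RunConfig, calibrate_default_config, run_pipeline)

cfg = calibrate_default_config(n=5000, seed=1)   # defaults = study conditions
report = run_pipeline(RunConfig(cohort_config=cfg, shift=0.9, outdir="out"))

c = report["concordance"]
print(f"concordance {c['percent_agreement']:.1f}% on {c['n_compared']}")
for d in report["diagnostics"]:
    print(d["stratum"], f"sens {d['sensitivity']:.3f} spec {d['specificity']:.3f}")
print("HbA1c deficit", round(report["hba1c_shift"]["difference"], 2), "%")
```

prints

```
concordance 100.0% on 1606
DEFICIENT sens 0.097 spec 1.000
NORMAL sens 0.612 spec 0.780
HbA1c deficit 0.87 %
```

Read: with no assay masking, genotype-predicted and assay-measured deficiency
agree perfectly on the 1606 participants with both (heterozygous women
excluded); HbA1c finds almost no abnormal glucose tolerance in the deficient
stratum while performing near the expected ~60%/78% with normal activity; and
the pipeline recovers the injected 0.9% HbA1c deficit. The packaged fixture
of the observed cohort's counts reproduces the published fractions exactly:

```python
from g6pdhb import evaluate_confusion_fixture
for d in evaluate_confusion_fixture():
    print(d.stratum, d.sensitivity, d.specificity)
# DEFICIENT 0.0 1.0
# NORMAL 0.5025641025641026 0.7977941176470589
```

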