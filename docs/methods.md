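# Methods

## Problem

Glycated hemoglobin (HbA1c) summarises ~2–3 months of glycemia and is widely
used to screen for abnormal glucose tolerance (Abnl-GT: prediabetes or type 2
diabetes) at the ≥ 5.7% / ≥ 6.5% thresholds. HbA1c is only meaningful when
red cells live a normal lifespan. Glucose-6-phosphate dehydrogenase (G6PD)
deficiency — common in people of African ancestry via the X-linked *G6PD* A-
haplotype — shortens red-cell lifespan through chronic low-grade hemolysis,
depressing HbA1c by roughly 0.9% *without any change in glycemia*. In a
cohort of sub-Saharan African immigrants (the Africans in America study),
this produced HbA1c sensitivity of 0% (0/17) for OGTT-defined Abnl-GT among
deficient participants, versus 50% (98/195) with normal enzyme activity.

This package implements that analysis as a tested pipeline: haplotype calling
from genotypes, deficiency-status resolution from genotype and/or enzymatic
assay, OGTT/HbA1c classification, stratified diagnostics, the mean-shift
re-evaluation, and a calibrated synthetic cohort generator so every stage is
exercisable without individual-level study data (none is deposited).

## Haplotype calling

The A- haplotype is the background allele rs1050829-C plus at least one
causal allele: rs1050828-T (~95% of carriers), rs76723693-C, or
rs137852328-A. Calling is sex-specific because *G6PD* is X-linked:

* **Men** (one X): A- iff hemizygous for rs1050829-C and hemizygous for ≥ 1
  causal allele. A genuinely heterozygous diploid male genotype is an
  `ERROR`; `0/0`-, `1/1`-style encodings of hemizygous calls are normalised
  to dosage 0/1.
* **Women**: A- iff homozygous for rs1050829-C and homozygous for ≥ 1 causal
  allele; carrying ≥ 1 copy of both without satisfying the homozygous rule is
  `HET_INDETERMINATE` — random X-inactivation makes the enzymatic phenotype
  of heterozygotes unpredictable from genotype.

**Missing data.** The calling rule is evaluated under every completion of the
missing dosages; the call is returned only if all completions agree,
otherwise `MISSING`. This uses partial genotypes maximally without guessing
and is a policy of this package (sources describing the cohort do not state
one). The test suite checks the caller against an independently written
transcription of the rules over the exhaustive dosage enumeration.

**Haplotype-inconsistent genotypes** (causal dosage exceeding the rs1050829
dosage) are called by the literal rule and annotated, since causal alleles
essentially never occur off the rs1050829-C background; no automatic strand
complementing is ever applied to risk alleles.

**Single-variant screen.** Genotyping only rs1050828 is a common expedient;
rs1050829-C is presumed present when rs1050828-T is seen. Its misses are
one-directional and are exactly the A- haplotypes carried by the two rare
causal variants — `compare_screening_strategies` quantifies this per cohort.

## Status resolution and concordance

The qualitative fluorescence assay measures the phenotype, so a performed
assay always determines status; disagreements with genotype are logged
(discordance policy of this package — the study observed none). Without an
assay, only decisive haplotype calls resolve; heterozygous women, erroneous
and missing genotypes are `INDETERMINATE` and excluded from prevalence and
diagnostic tables (with accounting). Concordance is percent agreement on
participants with both channels, heterozygous women excluded; Cohen's kappa
is reported alongside and defined as 1.0 under perfect agreement even with a
degenerate margin.

## Diagnostics

Sensitivity tp/(tp+fn) and specificity tn/(tn+fp) of the HbA1c flag against
OGTT Abnl-GT, per G6PD stratum, with Wilson score intervals (chosen for sane
behaviour at 0/n and n/n; the counts 0/17 and 37/37 are the motivating case).
Metrics with zero denominators are `None`, never 0. Group comparisons follow
the study's battery: Welch t (the "unpaired t-test" is not further specified,
so the unequal-variance form is the default), Mann–Whitney, chi-square
(no Yates correction, matching common statistical-package defaults), and
one-way ANOVA with uncorrected pairwise Welch tests labelled a/b/c
(West-vs-East / West-vs-Central / East-vs-Central); a Bonferroni option
exists.

**Mean-shift re-evaluation.** Deficient participants' HbA1c values are
incremented by the estimated group deficit (default 0.9%) and reclassified at
the unchanged threshold — algebraically identical to lowering the threshold
by the shift for that stratum only. HbA1c threshold comparisons use a 1e-9
absolute tolerance so this identity holds exactly in floating point; clinical
data at 0.1% resolution is unaffected. The observed cohort's adjusted figures
(70.6%/81%) require its unpublished individual-level values, so the package
checks this re-evaluation directionally (sensitivity never decreases,
specificity never increases) and via the threshold-equivalence property.

## Synthetic cohort generator

Defaults emulate the cohort's published structure; all are configuration, not
code:

| parameter | default | basis |
|---|---|---|
| male fraction | 0.61 | cohort demographics |
| region weights | West .47 / East+South .39 / Central .14 | cohort demographics |
| region q | solves 0.61q + 0.39q² = {.16, .05, .08} | regional deficiency prevalence under X-linked Hardy–Weinberg |
| causal mix | rs1050828 .95 / rs76723693 .04 / rs137852328 .01 | carrier counts |
| glycemic states | NGT .59 / prediabetes .3321 / T2D .0779 | 41% Abnl-GT, T2D ≈ 19% of Abnl-GT |
| HbA1c model | α + β·latent + δ·1{deficient} + N(0, σ); β = .45, τ = .3, δ = −0.9 | normal group 5.5 ± 0.6%, deficit −0.9% |
| reticulocyte % | N(2.92, .61) vs N(1.45, .42) | hemolysis markers |
| reticulocyte abs | N(94.1, 27.6) vs N(70.4, 20.6) | hemolysis markers |
| assay masking | 0 (per sex) | non-malarial setting |
| het-female phenotype P(deficient) | 0.5 | X-inactivation coin flip; a modeling choice, no published estimate |
| genotype missing / assay done | .155; .42 if genotyped, .87 if not | provenance mix genotype-only/assay-only/both ≈ 49/16/35% |

Glucose is drawn per glycemic state by vectorised rejection from
state-conditional normals, so integer-rounded values classify exactly into
the intended state at the 100/126/140/200 mg/dL boundaries. A latent glycemia
scale (state mean plus N(0, τ)) drives HbA1c; α and σ are set analytically in
`calibrate_default_config` so the normal-activity group has mean 5.5% and SD
0.6% given the state mix — the deficit δ applies to HbA1c only, since
hemolysis shortens red-cell lifespan without changing glycemia (the study saw
no glucose difference between groups). With β = 0.45 the emergent
normal-stratum sensitivity/specificity land near the observed 50%/80%; these
are emergent, not enforced. HbA1c is reported at 0.1% resolution.

The assay observes the deficiency *phenotype* — heterozygous women are
phenotype-deficient with probability 0.5 — and can be flipped to normal with
a per-sex masking probability, emulating the malaria-context discordance
(10% of hemizygous men, 24% of homozygous women with normal measured
activity) reported in other settings.

**What the generator does not emulate:** age/BMI structure, hemoglobinopathy
genetics beyond a flat exclusion flag, the real joint distribution of glucose
and HbA1c within states (only group means/SDs and prevalences are calibration
targets), enzyme-activity levels, or malaria dynamics. Passing recovery tests
therefore show that the pipeline estimates what the generator injects, not
that the generator reproduces every feature of real data. Because
heterozygous women are phenotype-deficient with probability 0.5, simulated
female deficiency prevalence (~12%) exceeds the study's 5%; lowering that
probability would trade one emulation target against another and we keep the
neutral coin flip.

## Numerical choices and sizes

* All randomness flows from a single `numpy` Generator seeded per run;
  identical config + seed gives byte-identical files and reports.
* Analyses and tests use n = 5000 cohorts (n = 20,000 where a prevalence is
  checked against a 3-binomial-SD band); parameter-recovery checks use five
  seeds at n = 5000 and ±0.1 tolerances on group means and the injected
  shift.
* Glucose plausibility bounds (20–800 mg/dL) warn rather than reject; HbA1c
  outside (2, 20)% is rejected.
* Exclusions are applied in order (missing OGTT/HbA1c, hemoglobinopathy,
  indeterminate status) with one reason logged per participant, so
  `n_input = n_retained + n_excluded` always holds.

## Known limitations

* The caller handles exactly the four A- sites; other *G6PD* alleles
  (Mediterranean, A+ alone) are out of scope, as are imputation and phasing.
* Kappa and Wilson intervals are reported even though the motivating study
  published only point fractions; they are conveniences, not replications.
* The generator's independence assumptions (region ⊥ sex, state-conditional
  glucose ⊥ HbA1c noise) are simplifications; real cohorts correlate these.
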