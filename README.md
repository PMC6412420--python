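# lgiob

A genetic score of predisposition to **l**ow-**g**rade **i**nflammation
associated with **ob**esity (LGI-Ob), together with the full analysis
pipeline built around it: derived anthropometric/lipid indices,
metabolic-risk classification, the ΔEPG omega-3 response statistic from
PBMC cultures, and the association stage (stratified correlations,
adjusted logistic odds ratios, ROC/AUC) — all testable end to end against
a bundled synthetic-cohort generator with known ground truth.

The package is aimed at nutrigenetics / genetic-epidemiology analysts who
want to apply or stress-test small additive genotype-weight scores against
metabolic-syndrome outcomes.

## The score

Five common SNPs, each tagging a gene involved in inflammation or
obesity-related metabolic disturbance, carry integer risk weights per
genotype:

| rsID       | gene  | genotypes → weights     |
|------------|-------|-------------------------|
| rs1800629  | TNFα  | GG=0, GA=2, AA=2 (dominant) |
| rs5082     | APOA2 | CC=0, TC=1, TT=2        |
| rs4880     | SOD2  | CC=0, CT=1, TT=2        |
| rs1260326  | GCKR  | CC=0, CT=1, TT=2        |
| rs9939609  | FTO   | TT=0, TA=1, AA=2        |

The score of a subject is the sum of the five weights, S ∈ {0,…,10};
subjects are dichotomized as low (S < 5) vs high (S ≥ 5).  Downstream the
pipeline computes BMI, WtHR = waist/height, MAP = ⅔·DBP + ⅓·SBP,
Friedewald LDLc = TC − (HDLc + TG/5) and TG/HDLc; classifies hypertension,
dyslipidemia, type-2 diabetes and visceral obesity with inclusive
thresholds (SBP ≥ 130 / DBP ≥ 80 mmHg; WtHR ≥ 0.51 women / 0.53 men);
defines metabolic risk MR as ≥ 2 of those four conditions; and estimates
adjusted odds ratios OR = exp(β) for high vs low stratum plus the ROC AUC
of the score against MR.  The PBMC response statistic is
ΔEPG = ΔIL6 + ΔTNFα, the summed treated-minus-control change of
RPLP0-normalized pro-inflammatory gene expression under DHA or EPA (more
negative = stronger anti-inflammatory response).

## Worked example

Simulate a cohort of 376 adults under the generator's default conditions
and run the complete pipeline:

```bash
lgiob run --simulate-n 376 --seed 7 --out run376
lgiob report --run-dir run376
```

prints

```
panel LGI-Ob v1.0, threshold 5, confounders methods
scores: n=376 median=4.0 mean=4.38 sd=1.70
OR[DL] = 1.35 (0.77-2.36), p=0.298, n=376
OR[HT] = 1.63 (1.05-2.51), p=0.0287, n=376
OR[MR] = 1.74 (1.07-2.85), p=0.026, n=376
OR[T2D] = 3.14 (1.33-7.42), p=0.00902, n=376
OR[VO] = 1.40 (0.91-2.13), p=0.123, n=376
MR ROC AUC = 0.551 (0.488-0.613), p=0.114
  without FTO: AUC = 0.540 (delta -0.011)
```

Reading this: the simulated score distribution matches the calibrated
population moments (median 4, mean ≈ 4.36, SD ≈ 1.7); high-score subjects
show significantly elevated adjusted odds of hypertension, type-2
diabetes and overall metabolic risk, while the score's single-cohort
discrimination for MR is modest (AUC ≈ 0.55 at this sample size) and drops
slightly when the FTO SNP is removed from the panel.  The run directory
holds `scores.tsv`, `derived.tsv`, `odds_ratios.tsv` and the full
`report.json` including the analysis ledger (which test was chosen by the
normality gate, which covariates entered each model, each analyzed n).

The same pipeline runs on real data: a genotype table or VCF plus a
phenotype CSV (`lgiob run --genotypes g.tsv --phenotypes p.csv --out d`);
`lgiob simulate`, `score`, `derive`, `classify` and `associate` expose the
individual stages.

Library use:

```python
from lgiob import SimConfig, simulate_cohort, default_panel, compute_score

sim = simulate_cohort(SimConfig(n=1000, seed=1))      # cohort + hidden truth
res = compute_score(sim.cohort.genotypes[0], default_panel())
print(res.score, res.stratum, res.breakdown)
```

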