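# Methods

## The score and its contract

The LGI-Ob score is an additive, integer-weighted genotype score over five
unlinked biallelic SNPs (TNFα rs1800629, APOA2 rs5082, SOD2 rs4880, GCKR
rs1260326, FTO rs9939609).  Weights are per-genotype, not per-allele:
four SNPs use the additive coding 0/1/2, while rs1800629 uses a dominant
coding (0/2/2) in which heterozygotes carry the full risk weight.  The
weights ship as data (`src/lgiob/data/default_panel.json`), so the engine
is reusable for any other small genotype-weight score; the engine itself
only assumes three genotypes per SNP and integer weights in {0,1,2}.

Genotypes are unordered: calls are normalized to an alphabetically sorted
allele pair on input, and every call is validated against the panel's
declared allele set.  No strand flipping is ever attempted — rs9939609 is
a T/A site, where a silent flip is undetectable and is the classic genetic
risk score bug — so mismatched allele labels fail loudly instead.
Subjects missing any panel genotype are flagged unscorable rather than
scored low, and the complete-case join drops them with a count recorded
in provenance.  Per-SNP imputation is deliberately not offered.

Dichotomization uses a fixed cut of 5 ("low" < 5 ≤ "high") by default,
reflecting the population median of 4 for this panel; a `median` policy
recomputes the cut as the smallest integer above the current cohort's
median for users applying the engine to other panels or populations.

## Derived indices and risk classification

BMI = weight/height² (kg/m²); WtHR = waist/height; MAP = ⅔·DBP + ⅓·SBP;
Friedewald LDLc = TC − (HDLc + TG/5), flagged unreliable above
TG 400 mg/dL (the formula's standard validity limit) or when negative;
TG/HDLc as an insulin-resistance proxy.  All computation is carried at
full precision; table-style rounding (MAP 1 dp, WtHR 2 dp) is applied only
at display time.

The four condition rules are inclusive at their thresholds (SBP ≥ 130,
DBP ≥ 80 mmHg, WtHR ≥ 0.51 women / 0.53 men) and each is a disjunction of
diagnosis, medication and measurement branches.  Missing inputs propagate
under Kleene three-valued logic: a flag is false only when every branch is
affirmatively false, undetermined otherwise.  Undetermined flags are
excluded from the alteration count (with a warning), and MR
(= ≥ 2 alterations) is undetermined only when all four flags are.  This
biases n_alterations downward under missingness — the conservative
direction for a "high risk" label — and is reported rather than hidden.

## ΔEPG

Expression of IL6 and TNFα in cultured PBMC is normalized to the
housekeeping gene RPLP0 as a linear ratio; each fatty-acid treatment (DHA,
EPA, separately) is contrasted against the untreated control of the same
subject, and ΔEPG is the sum of the two gene deltas.  Whether such a
summary should use linear differences or a log2 scale is genuinely open;
the linear difference is the default because only delta magnitudes, not
signs, differ between the scales, and the downstream conclusions rest on
signs and rank correlations.  A `scale="log2"` hook is provided.
Cytokine concentrations are compared control-vs-treated by a paired
Student t-test within score strata (the default contrast); a two-way
repeated-measures ANOVA on the difference scores is available as an
alternative, and reports always name the contrast used.

## Association stage

Normality gating follows the classical recipe: Shapiro–Wilk below n = 50,
Kolmogorov–Smirnov from 50 up — implemented as the Lilliefors-corrected
variant, since distribution parameters are estimated from the data and
the plain KS null would be anticonservative.  On rejection a log
transform is attempted (blocked by nonpositive values), then the route
falls back to nonparametric.  Every gate decision is recorded in the run's
analysis ledger because the method choice is data-dependent and
reproducibility requires it be logged.

Age-adjusted correlations are computed by residualization: x and y are
each regressed on the covariates (with intercept) and the Pearson
correlation of the residuals is reported with df = n − 2 − k.  With no
covariates this reduces exactly to plain Pearson; the residualization and
classical-partial definitions coincide here, and the implementation is
cross-checked against an independent partial-correlation routine in the
tests.

The logistic fit is an in-house IRLS (tolerance 1e-8 on the coefficient
step, max 50 iterations).  Complete or quasi-separation is detected by
divergence of the coefficient norm (cap |β| = 30 on the logit scale) and
raised as an error with a diagnostic instead of silently returning a huge
OR.  The odds ratio is exp(β) for the high-vs-low stratum indicator with
Wald CIs on the log-odds scale.  Two confounder presets ship — age, sex,
overweight and ethnicity (the default, with overweight automatically
excluded for the visceral-obesity outcome, which it would near-alias), or
age, sex and ethnicity — and the report names the set used.  Ethnicity
enters as one-hot dummies with levels under 10 subjects collapsed into the
modal category, avoiding quasi-separation on a nuisance covariate in
small cohorts.

ROC AUC uses the rank (Mann–Whitney) formulation with midrank tie
handling — essential because an integer score on {0..10} is heavily
tied — with DeLong placement-value variance for the CI and the normal
approximation for H0: AUC = 0.5.  A seeded bootstrap CI (2000 resamples)
is not included; DeLong is standard and cheaper.

No multiple-testing correction is applied anywhere; analyses are reported
singly at two-sided α = 0.05, and pooled and stratified versions of the
correlation analyses are always both emitted.

## Synthetic cohorts

The generator exists so every stage is testable without access to any
real cohort; its defaults are fixed study conditions, not tuning knobs.

**Genotypes.** Independent SNPs under Hardy–Weinberg equilibrium
(genotype probabilities p², 2pq, q²).  No linkage disequilibrium is
modeled: the five loci lie in different genomic regions and the score
treats them additively.  Default allele frequencies come from
`calibrate_frequencies`, which root-finds a single shared risk-allele
frequency such that the exact HWE expectation of the score
(E[S] = Σ_snp Σ_g w(g)·P_HWE(g), a quadratic 12q − 2q² for this panel)
equals the published population mean 4.36.  The solution q ≈ 0.3885 also
reproduces the published SD (≈ 1.68 vs 1.7) and median (4) without any
additional freedom — the score distribution is pinned by one parameter.

**Phenotypes.** Demographics follow the published cohort description
(63% female, age 36 ± 15 clipped to 18–90, 86.4% European); the
overweight fraction is 41%, with BMI drawn from a two-component truncated
normal mixture (22.3 ± 1.8 below 25; 29.5 ± 4 above).  Each disorder d is
drawn from logit P = α_d + ln(OR_d)·1[high] + 0.5·z_age + 0.2·male, with
α_d set so the marginal prevalence hits its target (HT 0.30, DL 0.15,
T2D 0.06, VO 0.40 — plausible adult prevalences, pure configuration, no
claim of matching any particular cohort).  Default ORs anchor to the
published significant estimates (HT 1.58, T2D 3.26); DL and VO were
reported only as non-significant forest-plot entries, so their defaults
(1.2, 1.3) are modest values consistent with that.  MR is never
simulated — it emerges from the four flags, which are conditionally
independent given covariates (their true comorbidity structure is
unreported; this suffices for recovery tests but is not a cohort claim).

Measurements are then generated *consistently with the flags*: untreated
hypertensive subjects receive SBP/DBP beyond the classification
thresholds, non-hypertensive subjects below them; visceral obesity maps
to WtHR beyond the sex-specific cut (with a 0.005 margin so 0.1 cm waist
rounding cannot flip the class), and waist is back-computed from WtHR and
height.  Classifying the simulated phenotypes therefore recovers the
latent flags exactly, which the tests assert.

**Inflammation and lipids.** CRP is lognormal (σ = 0.8) with an
overweight offset matching the published group means (0.67 vs 1.73 ng/mL)
and a score slope *active only in the overweight stratum*; the default
slope 0.27/score-point is back-solved so the implied overweight-stratum
partial correlation is ≈ 0.50, the published value.  TG is lognormal with
an overweight offset and an overweight-only score slope (0.14, implying
r ≈ 0.42 for TG/HDLc vs score).  The normal-weight slopes are zero, which
is what makes the stratified correlation pattern a recoverable truth.

**Omega-3 response.** ΔEPG_i = μ + γ·S_i + ε with μ = −3 (baseline
anti-inflammatory response), γ = 0.3 (attenuation with genetic load, zero
expected response at the maximum score) and σ = 0.7, giving a pooled
score–ΔEPG correlation around 0.6.  Gene deltas split ΔEPG ≈ 55/45
between IL6 and TNFα; raw expression values are reconstructed so that the
response module re-derives the latent ΔEPG (up to 4-dp rounding of raw
values, and with treated expression floored at zero — an absent
transcript — in the rare extreme tail).  Cytokine deltas share the sign
of the expression deltas.

All draws descend from one root seed through named `SeedSequence` spawns
(genotypes, demographics, adiposity, disorders, biomarkers, missingness,
expression), so identical configs are bit-identical and components are
independently re-drawable.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and population
structure, comorbidity correlations between disorders, genotyping error,
measurement error correlated across visits, medication effects on
biomarkers, and any real joint distribution of adiposity with age beyond
the configured marginals.  Recovery tests validate the *estimators*, not
the biology.

## Problem sizes in the checks

The verification suite uses cohorts of n = 5000 (100 seeds) for OR
coverage, n = 2000 (10 seeds) for null calibration, n = 50 000 for the
HWE calibration check and n = 1000 (20 seeds) for the stratified
correlation pattern — sizes at which the Monte-Carlo error of each check
is small relative to its acceptance band while the whole suite stays
desk-scale.

## Known limitations

* Friedewald LDLc is reported per subject; group-mean LDLc computed from
  group-mean inputs differs slightly (nonlinear missingness patterns), so
  published group LDLc means are not used for validation.
* The Wald OR CI is first-order; with very sparse outcomes
  profile-likelihood intervals would be preferable and are not provided.
* The DeLong p-value for AUC = 0.5 is asymptotic; at very small n the
  exact permutation null would differ.
* `group_compare` reports the mean difference on the original scale even
  when the gate routes through a log transform (the test is then on the
  log scale, flagged in the result).
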