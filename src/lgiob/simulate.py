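"""Synthetic-cohort generator with the statistical structure the analysis assumes.

Genotypes are drawn per SNP under Hardy-Weinberg equilibrium with
independent loci (the five panel genes sit in unlinked regions and the
score treats them additively).  Default allele frequencies are not free
parameters: they are calibrated so that the exact HWE expectation of the
score reproduces the printed population moments of the score distribution
(median 4, mean 4.36, SD ~1.7 on the 0-10 support).

Phenotypes are layered on top of the scored genotypes:

* demographics - 63% female, age ~ N(36, 15) clipped to adulthood,
  ethnicity 86.4% European;
* adiposity - overweight/obese fraction 41% (BMI >= 25), BMI drawn from a
  two-component truncated-normal mixture;
* disorders - HT/DL/T2D/VO drawn from logistic models
  logit P = alpha_d + ln(OR_d) * 1[high stratum] + age and sex terms, with
  blood pressure and waist values generated consistently with the flags'
  classification thresholds, so classifying the simulated phenotypes
  recovers the latent flags;
* inflammation - CRP lognormal with a score slope active only in the
  overweight stratum; TG/HDLc with an overweight-only score slope;
* omega-3 response - dEPG_i = mu + gamma * score_i + eps, mu < 0 (a
  baseline anti-inflammatory response) and gamma > 0 (attenuation with
  genetic load).

Default effect sizes are anchored to the observed associations: OR 1.58
for hypertension and 3.26 for type 2 diabetes, and stratum slopes
back-solved from the printed overweight-stratum correlations (r ~ 0.50 for
CRP, ~ 0.42 for TG/HDLc).  Metabolic risk (MR) is never simulated
directly; it emerges from the four condition flags.

Every draw flows from one root seed through named ``SeedSequence`` spawns
(one stream per component), so identical configs give bit-identical
cohorts and changing one component's stream leaves the others untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import Cohort, GenotypeRecord
from .panel import SnpPanel, default_panel
from .score import DEFAULT_THRESHOLD, score_table

__all__ = [
    "SimConfig",
    "SimulatedCohort",
    "simulate_genotypes",
    "calibrate_frequencies",
    "analytic_score_mean",
    "analytic_score_distribution",
    "simulate_phenotypes",
    "simulate_expression_response",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults are the study conditions."""

    n: int = 376
    seed: int = 0
    allele_freqs: dict | None = None  # rsID -> risk-allele frequency; None = calibrated
    score_threshold: int = DEFAULT_THRESHOLD

    # demographics
    female_frac: float = 0.63
    age_mean: float = 36.0
    age_sd: float = 15.0
    ethnicity_probs: dict = field(default_factory=lambda: {
        "european": 0.864, "south_american": 0.11, "other": 0.026})

    # adiposity
    overweight_frac: float = 0.41

    # disorder models: target OR (high vs low stratum) and base prevalence
    or_ht: float = 1.58
    or_dl: float = 1.2
    or_t2d: float = 3.26
    or_vo: float = 1.3
    prev_ht: float = 0.30
    prev_dl: float = 0.15
    prev_t2d: float = 0.06
    prev_vo: float = 0.40
    beta_age: float = 0.5  # per age SD, shared log-odds slope
    beta_male: float = 0.2

    # inflammation / lipids (log scale)
    crp_slope_ow: float = 0.27  # per score point, overweight stratum only
    crp_slope_nw: float = 0.0
    crp_sigma: float = 0.8
    tg_hdl_slope_ow: float = 0.14
    tg_sigma: float = 0.45

    # omega-3 PBMC response
    epg_mu: float = -3.0
    epg_gamma: float = 0.3
    epg_sigma: float = 0.7

    # missingness (applied to optional phenotype columns)
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.allele_freqs is not None:
            bad = {r: q for r, q in self.allele_freqs.items() if not 0.0 <= q <= 1.0}
            if bad:
                raise ValueError(f"allele frequencies outside [0,1]: {bad}")
        for name in ("or_ht", "or_dl", "or_t2d", "or_vo"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulatedCohort:
    """A cohort plus the hidden truth used to score parameter recovery."""

    cohort: Cohort
    scores: pd.DataFrame
    truth: dict


def _streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# ---------------------------------------------------------------------------
# genotypes


def analytic_score_mean(freqs: dict, panel: SnpPanel | None = None) -> float:
    """Exact HWE expectation of the score: sum over SNPs of E[weight]."""
    panel = panel or default_panel()
    total = 0.0
    for snp in panel:
        q = freqs[snp.rsid]
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        total += sum(p * snp.weights[snp.genotype_for_risk_count(k)]
                     for k, p in enumerate(probs))
    return total


def analytic_score_distribution(freqs: dict, panel: SnpPanel | None = None) -> dict[int, float]:
    """Exact score pmf under HWE by convolving per-SNP weight distributions."""
    panel = panel or default_panel()
    pmf = {0: 1.0}
    for snp in panel:
        q = freqs[snp.rsid]
        probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
        nxt: dict[int, float] = {}
        for s, p0 in pmf.items():
            for k, pk in enumerate(probs):
                w = snp.weights[snp.genotype_for_risk_count(k)]
                nxt[s + w] = nxt.get(s + w, 0.0) + p0 * pk
        pmf = nxt
    return dict(sorted(pmf.items()))


def calibrate_frequencies(
    target_median: float = 4.0,
    target_mean: float = 4.36,
    panel: SnpPanel | None = None,
    tol: float = 0.05,
) -> dict[str, float]:
    """Find allele frequencies whose exact HWE score mean hits the target.

    A single shared risk-allele frequency is searched by root finding on
    the analytic mean (monotone increasing in q), which pins the generator
    to the only distributional facts available for the score.  Raises if
    the target mean is outside [0, panel maximum], reporting the nearest
    achievable value, and warns when the implied exact median misses
    ``target_median``.
    """
    panel = panel or default_panel()
    lo, hi = 0.0, float(panel.max_score)
    if not lo - 1e-9 <= target_mean <= hi + 1e-9:
        nearest = min(max(target_mean, lo), hi)
        raise ValueError(
            f"target mean {target_mean} unattainable on [0, {panel.max_score}]; "
            f"nearest achievable value is {nearest}"
        )

    def mean_at(q: float) -> float:
        return analytic_score_mean({s.rsid: q for s in panel}, panel)

    if target_mean <= 0:
        q = 0.0
    elif target_mean >= hi:
        q = 1.0
    else:
        q = brentq(lambda v: mean_at(v) - target_mean, 0.0, 1.0, xtol=1e-12)
    freqs = {s.rsid: q for s in panel}
    achieved = analytic_score_mean(freqs, panel)
    if abs(achieved - target_mean) > tol:
        raise ValueError(f"calibration missed the target mean: {achieved} vs {target_mean}")
    pmf = analytic_score_distribution(freqs, panel)
    cdf, median = 0.0, None
    for s, p in pmf.items():
        cdf += p
        if cdf >= 0.5:
            median = s
            break
    if median != target_median:
        import warnings

        warnings.warn(f"calibrated frequencies give exact median {median}, "
                      f"target was {target_median}", stacklevel=2)
    return freqs


def simulate_genotypes(config: SimConfig, panel: SnpPanel | None = None,
                       rng: np.random.Generator | None = None) -> list[GenotypeRecord]:
    """Draw independent HWE genotypes for every subject at every panel SNP."""
    panel = panel or default_panel()
    freqs = config.allele_freqs or calibrate_frequencies(panel=panel)
    rng = rng or _streams(config.seed, ("genotypes",))["genotypes"]
    n = config.n
    counts = {}
    for snp in panel:
        q = freqs[snp.rsid]
        counts[snp.rsid] = rng.choice(3, size=n, p=[(1 - q) ** 2, 2 * q * (1 - q), q**2])
    records = []
    width = len(str(n))
    for i in range(n):
        calls = {
            snp.rsid: snp.genotype_for_risk_count(int(counts[snp.rsid][i]))
            for snp in panel
        }
        records.append(GenotypeRecord(f"S{i + 1:0{width}d}", calls))
    return records


# ---------------------------------------------------------------------------
# phenotypes


def _truncated_normal(rng, mean, sd, low, high, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def simulate_phenotypes(genotypes: list[GenotypeRecord], config: SimConfig,
                        panel: SnpPanel | None = None) -> SimulatedCohort:
    """Generate phenotypes conditional on the scored genotypes."""
    from .derive import HT_DBP, HT_SBP, VO_WTHR_FEMALE, VO_WTHR_MALE

    panel = panel or default_panel()
    rngs = _streams(config.seed, (
        "genotypes", "demographics", "adiposity", "disorders", "biomarkers", "missing"))
    n = len(genotypes)
    scores = score_table(genotypes, panel, config.score_threshold)
    score = scores["score"].to_numpy(dtype=float)
    high = (scores["stratum"] == "high").to_numpy()

    rng = rngs["demographics"]
    female = rng.random(n) < config.female_frac
    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 18, 90)
    eth_names = list(config.ethnicity_probs)
    probs = np.asarray(list(config.ethnicity_probs.values()), dtype=float)
    ethnicity = rng.choice(eth_names, size=n, p=probs / probs.sum())
    height = np.where(female,
                      rng.normal(1.62, 0.065, n),
                      rng.normal(1.76, 0.07, n)).round(3)

    rng = rngs["adiposity"]
    if config.overweight_frac <= 0 and (config.crp_slope_ow or config.tg_hdl_slope_ow):
        import warnings

        warnings.warn("overweight fraction is 0 but overweight-conditional effects are set",
                      stacklevel=2)
    ow = rng.random(n) < config.overweight_frac
    bmi_vals = np.where(
        ow,
        _truncated_normal(rng, 29.5, 4.0, 25.0, 50.0, n),
        _truncated_normal(rng, 22.3, 1.8, 16.5, 24.99, n),
    )
    weight = bmi_vals * height**2

    rng = rngs["disorders"]
    zage = (age - config.age_mean) / config.age_sd
    male = (~female).astype(float)
    p_high = float(high.mean())
    flags = {}
    for name, or_d, prev in (
        ("ht", config.or_ht, config.prev_ht),
        ("dl", config.or_dl, config.prev_dl),
        ("t2d", config.or_t2d, config.prev_t2d),
        ("vo", config.or_vo, config.prev_vo),
    ):
        alpha = logit(prev) - np.log(or_d) * p_high
        eta = alpha + np.log(or_d) * high + config.beta_age * zage + config.beta_male * male
        flags[name] = rng.random(n) < expit(eta)

    # hypertension: diagnosis/medication and blood pressure consistent with the flag
    ht = flags["ht"]
    ht_dx = ht & (rng.random(n) < 0.35)
    ht_med = ht_dx & (rng.random(n) < 0.7)
    # untreated flagged subjects must exceed a pressure threshold
    need_bp = ht & ~ht_dx
    high_sbp_branch = rng.random(n) < 0.8
    sbp = np.where(ht, np.where(high_sbp_branch,
                                HT_SBP + np.abs(rng.normal(8, 10, n)),
                                HT_SBP - np.abs(rng.normal(6, 5, n))),
                   np.clip(HT_SBP - 1 - np.abs(rng.normal(10, 9, n)), 95, None))
    dbp = np.where(ht, np.where(high_sbp_branch,
                                np.clip(HT_DBP + rng.normal(2, 8, n), 55, None),
                                HT_DBP + np.abs(rng.normal(4, 5, n))),
                   np.clip(HT_DBP - 1 - np.abs(rng.normal(6, 6, n)), 55, None))
    # treated-and-controlled subjects may sit below the thresholds
    controlled = ht_med & (rng.random(n) < 0.5)
    sbp = np.where(controlled & ~need_bp, np.clip(sbp - 15, 100, None), sbp)
    sbp = np.round(np.maximum(sbp, dbp + 10), 1)
    dbp = np.round(dbp, 1)

    dl = flags["dl"]
    dl_dx = dl & (rng.random(n) < 0.75)
    dl_med = dl & (~dl_dx | (rng.random(n) < 0.4))

    t2d = flags["t2d"]
    t2d_dx = t2d & (rng.random(n) < 0.8)
    t2d_med = t2d & (~t2d_dx | (rng.random(n) < 0.6))

    vo = flags["vo"]
    vo_cut = np.where(female, VO_WTHR_FEMALE, VO_WTHR_MALE)
    # 0.005 margin keeps the flag stable under 0.1 cm waist rounding
    wthr_vals = np.where(vo,
                         vo_cut + 0.005 + np.abs(rng.normal(0.035, 0.04, n)),
                         np.clip(vo_cut - 0.02 - np.abs(rng.normal(0.05, 0.05, n)), 0.35, None))
    waist = np.round(wthr_vals * height * 100, 1)
    hip = np.round(waist + rng.normal(9, 4, n), 1)

    rng = rngs["biomarkers"]
    score_c = score - score.mean()
    glucose = np.clip(rng.normal(92, 12, n) + 30 * t2d, 60, None).round(1)
    tc = np.clip(rng.normal(190, 42, n) + 12 * dl, 90, None).round(2)
    hdlc = np.clip(rng.normal(60, 14, n), 25, None).round(2)
    log_tg = (np.log(105) + 0.30 * ow + config.tg_hdl_slope_ow * score_c * ow
              + rng.normal(0, config.tg_sigma, n))
    tg = np.clip(np.exp(log_tg), 30, None).round(2)
    log_crp = (np.log(0.67) + np.log(1.73 / 0.67) * ow
               + config.crp_slope_ow * score_c * ow
               + config.crp_slope_nw * score_c * ~ow
               + 0.1 * zage + rng.normal(0, config.crp_sigma, n))
    crp = np.exp(log_crp).round(4)

    phen = pd.DataFrame({
        "subject_id": [g.subject_id for g in genotypes],
        "age": age.round(1),
        "sex": np.where(female, "female", "male"),
        "ethnicity": ethnicity,
        "height": height,
        "weight": weight.round(1),
        "waist": waist,
        "hip": hip,
        "sbp": sbp,
        "dbp": dbp,
        "glucose": glucose,
        "tc": tc,
        "hdlc": hdlc,
        "tg": tg,
        "crp": crp,
        "ht_dx": ht_dx,
        "dl_dx": dl_dx,
        "t2d_dx": t2d_dx,
        "antihypertensive_med": ht_med,
        "lipid_lowering_med": dl_med,
        "antidiabetic_med": t2d_med,
    })
    for col in ("ht_dx", "dl_dx", "t2d_dx", "antihypertensive_med",
                "lipid_lowering_med", "antidiabetic_med"):
        phen[col] = phen[col].astype("boolean")

    if config.missing_rate > 0:
        rng_m = rngs["missing"]
        for col in ("waist", "hip", "glucose", "tc", "hdlc", "tg", "crp"):
            mask = rng_m.random(n) < config.missing_rate
            phen.loc[mask, col] = np.nan

    truth = {
        "or": {"HT": config.or_ht, "DL": config.or_dl, "T2D": config.or_t2d,
               "VO": config.or_vo},
        "beta_age": config.beta_age,
        "beta_male": config.beta_male,
        "crp_slope_ow": config.crp_slope_ow,
        "crp_slope_nw": config.crp_slope_nw,
        "tg_hdl_slope_ow": config.tg_hdl_slope_ow,
        "latent_flags": {"HT": ht, "DL": dl, "T2D": t2d, "VO": vo},
        "overweight": ow,
    }
    cohort = Cohort(list(genotypes), phen,
                    provenance={"source": "simulated", "seed": config.seed,
                                "panel": panel.name, "n": n})
    return SimulatedCohort(cohort, scores, truth)


# ---------------------------------------------------------------------------
# expression / cytokines


def simulate_expression_response(scores: pd.DataFrame, config: SimConfig) -> dict:
    """Generate PBMC expression and cytokine tables consistent with the scores.

    Returns ``{"expression": long_df, "cytokines": long_df, "truth": dict}``
    in the exact long formats :mod:`lgiob.response` reads.  The latent
    per-subject response is dEPG = mu + gamma * score + eps for each fatty
    acid; gene deltas split it ~55/45 between IL6 and TNFA, and cytokine
    deltas share its sign.
    """
    from .response import TREATMENTS

    rng = _streams(config.seed, ("genotypes", "demographics", "adiposity",
                                 "disorders", "biomarkers", "missing", "expression"))["expression"]
    sids = scores["subject_id"].tolist()
    score = scores["score"].to_numpy(dtype=float)
    n = len(sids)

    expr_rows, cyt_rows = [], []
    truth_epg: dict[str, np.ndarray] = {}
    # control condition: normalized IL6/TNFA around 4 on the RPLP0 scale, so
    # anti-inflammatory deltas of a few units keep treated expression positive
    rp_ctrl = np.maximum(50.0, rng.normal(100, 10, n)).round(4)
    ctrl_norm = {g: np.maximum(0.5, rng.normal(4.0, 0.5, n)) for g in ("IL6", "TNFA")}
    ctrl_conc = {"IL6": np.maximum(0.1, rng.normal(12.0, 2.4, n)).round(4),
                 "TNFA": np.maximum(0.1, rng.normal(35.0, 7.0, n)).round(4)}
    for i, sid in enumerate(sids):
        expr_rows.append((sid, "control", "RPLP0", float(rp_ctrl[i])))
        for g in ("IL6", "TNFA"):
            expr_rows.append((sid, "control", g, round(float(ctrl_norm[g][i] * rp_ctrl[i]), 4)))
            cyt_rows.append((sid, "control", g, float(ctrl_conc[g][i])))
    # exact control normalized values as the response module will recompute them
    ctrl_norm_exact = {
        g: np.array([round(float(ctrl_norm[g][i] * rp_ctrl[i]), 4) for i in range(n)]) / rp_ctrl
        for g in ("IL6", "TNFA")
    }
    for trt in TREATMENTS:
        depg = config.epg_mu + config.epg_gamma * score + rng.normal(0, config.epg_sigma, n)
        frac = np.clip(rng.normal(0.55, 0.05, n), 0.3, 0.7)
        deltas = {"IL6": frac * depg, "TNFA": (1 - frac) * depg}
        rp_trt = np.maximum(50.0, rng.normal(100, 10, n))
        realized = np.zeros(n)
        for g in ("IL6", "TNFA"):
            # an absent transcript floors treated expression at zero
            treated = np.maximum(0.0, ctrl_norm_exact[g] + deltas[g])
            deltas[g] = treated - ctrl_norm_exact[g]
            realized += deltas[g]
        truth_epg[trt] = realized
        for i, sid in enumerate(sids):
            expr_rows.append((sid, trt, "RPLP0", round(float(rp_trt[i]), 4)))
            for g in ("IL6", "TNFA"):
                treated_norm = ctrl_norm_exact[g][i] + deltas[g][i]
                expr_rows.append((sid, trt, g, round(float(treated_norm * rp_trt[i]), 4)))
                conc = max(0.0, float(ctrl_conc[g][i] + 2.0 * deltas[g][i] + rng.normal(0, 0.5)))
                cyt_rows.append((sid, trt, g, round(conc, 4)))

    expression = pd.DataFrame(expr_rows, columns=["subject_id", "treatment", "gene", "value"])
    cytokines = pd.DataFrame(cyt_rows, columns=["subject_id", "treatment", "cytokine", "value"])
    return {
        "expression": expression,
        "cytokines": cytokines,
        "truth": {"epg_mu": config.epg_mu, "epg_gamma": config.epg_gamma,
                  "delta_epg": truth_epg},
    }


def simulate_cohort(config: SimConfig, panel: SnpPanel | None = None,
                    with_expression: bool = False) -> SimulatedCohort:
    """One-call generator: genotypes, phenotypes and (optionally) expression."""
    panel = panel or default_panel()
    genotypes = simulate_genotypes(config, panel)
    sim = simulate_phenotypes(genotypes, config, panel)
    if with_expression:
        resp = simulate_expression_response(sim.scores, config)
        sim.truth["expression"] = resp["truth"]
        sim.cohort.provenance["expression"] = True
        sim.truth["_expression_tables"] = {k: resp[k] for k in ("expression", "cytokines")}
    return sim
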