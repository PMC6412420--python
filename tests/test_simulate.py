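"""Synthetic cohorts: determinism, Hardy-Weinberg structure, calibration,
and the generative links the association stage is meant to recover."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from lgiob.derive import classify_risk, derive_phenotypes
from lgiob.response import expression_response
from lgiob.simulate import (
    SimConfig,
    analytic_score_distribution,
    analytic_score_mean,
    calibrate_frequencies,
    simulate_cohort,
    simulate_expression_response,
    simulate_genotypes,
    simulate_phenotypes,
)
from lgiob.stats import partial_pearson


def test_determinism_bit_identical():
    cfg = SimConfig(n=300, seed=42)
    a = simulate_cohort(cfg, with_expression=True)
    b = simulate_cohort(cfg, with_expression=True)
    pd.testing.assert_frame_equal(a.cohort.phenotypes, b.cohort.phenotypes)
    pd.testing.assert_frame_equal(a.scores, b.scores)
    assert [r.calls for r in a.cohort.genotypes] == [r.calls for r in b.cohort.genotypes]
    pd.testing.assert_frame_equal(a.truth["_expression_tables"]["expression"],
                                  b.truth["_expression_tables"]["expression"])


def test_extreme_frequencies_force_score(panel):
    zero = SimConfig(n=50, seed=1, allele_freqs={r: 0.0 for r in panel.rsids})
    ten = SimConfig(n=50, seed=1, allele_freqs={r: 1.0 for r in panel.rsids})
    from lgiob.score import score_table

    s0 = score_table(simulate_genotypes(zero, panel), panel)["score"]
    s10 = score_table(simulate_genotypes(ten, panel), panel)["score"]
    assert (s0 == 0).all()
    assert (s10 == 10).all()


def test_hardy_weinberg_genotype_frequencies(panel):
    n = 20000
    freqs = calibrate_frequencies(panel=panel)
    cfg = SimConfig(n=n, seed=2024, allele_freqs=freqs)
    records = simulate_genotypes(cfg, panel)
    for snp in panel:
        q = freqs[snp.rsid]
        expected = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2]) * n
        counts = np.zeros(3)
        for rec in records:
            k = sum(a == snp.risk_allele for a in rec.calls[snp.rsid])
            counts[k] += 1
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert chi2 < sps.chi2.ppf(0.999, df=2)


def test_calibration_edges_and_error(panel):
    assert all(v == 0.0 for v in calibrate_frequencies(0, 0.0, panel).values())
    assert all(v == 1.0 for v in calibrate_frequencies(10, 10.0, panel).values())
    with pytest.raises(ValueError, match="nearest"):
        calibrate_frequencies(target_median=4, target_mean=11.0, panel=panel)


def test_calibrated_default_matches_analytic_and_monte_carlo(panel):
    freqs = calibrate_frequencies(panel=panel)
    mean = analytic_score_mean(freqs, panel)
    assert mean == pytest.approx(4.36, abs=1e-9)
    pmf = analytic_score_distribution(freqs, panel)
    assert sum(pmf.values()) == pytest.approx(1.0)
    sd = np.sqrt(sum(p * (s - mean) ** 2 for s, p in pmf.items()))
    from lgiob.score import score_table

    cfg = SimConfig(n=20000, seed=5, allele_freqs=freqs)
    scores = score_table(simulate_genotypes(cfg, panel), panel)["score"].astype(float)
    assert abs(scores.mean() - mean) < 3 * sd / np.sqrt(len(scores))
    assert set(scores.unique()) <= set(range(11))


def test_phenotypes_consistent_with_flags(panel):
    sim = simulate_cohort(SimConfig(n=3000, seed=9))
    derived = derive_phenotypes(sim.cohort.phenotypes)
    risk = classify_risk(derived)
    for name in ("HT", "DL", "T2D", "VO"):
        np.testing.assert_array_equal(
            risk[name].astype(bool).to_numpy(), sim.truth["latent_flags"][name],
            err_msg=f"classification does not recover the latent {name} flag")
    ow_frac = derived["overweight"].astype(bool).mean()
    assert ow_frac == pytest.approx(0.41, abs=0.03)


def test_overweight_conditional_crp_structure():
    sim = simulate_cohort(SimConfig(n=1500, seed=13))
    ph = sim.cohort.phenotypes
    score = sim.scores["score"].to_numpy(float)
    ow = sim.truth["overweight"]
    crp = np.log(ph["crp"].to_numpy(float))
    age = ph[["age"]]
    ow_res = partial_pearson(score[ow], crp[ow], age[ow])
    nw_res = partial_pearson(score[~ow], crp[~ow], age[~ow])
    assert ow_res.estimate > 0.3 and ow_res.p < 0.001
    assert abs(nw_res.estimate) < 0.12


def test_expression_null_and_power(panel):
    cfg_null = SimConfig(n=500, seed=3, epg_gamma=0.0)
    sim = simulate_cohort(cfg_null)
    resp = simulate_expression_response(sim.scores, cfg_null)
    epg = expression_response(resp["expression"])
    merged = epg[epg.treatment == "EPA"].merge(sim.scores, on="subject_id")
    r_null = partial_pearson(merged["score"].astype(float), merged["delta_epg"])
    assert abs(r_null.estimate) < 0.1

    cfg = SimConfig(n=200, seed=3)  # default gamma = 0.3
    sim2 = simulate_cohort(cfg)
    resp2 = simulate_expression_response(sim2.scores, cfg)
    epg2 = expression_response(resp2["expression"])
    merged2 = epg2[epg2.treatment == "EPA"].merge(sim2.scores, on="subject_id")
    r = partial_pearson(merged2["score"].astype(float), merged2["delta_epg"])
    assert r.estimate > 0.3 and r.p < 1e-4


def test_expression_tables_reconstruct_truth():
    cfg = SimConfig(n=120, seed=8)
    sim = simulate_cohort(cfg)
    resp = simulate_expression_response(sim.scores, cfg)
    assert (resp["expression"]["value"] >= 0).all()
    epg = expression_response(resp["expression"])
    for trt in ("DHA", "EPA"):
        recovered = epg[epg.treatment == trt].set_index("subject_id")["delta_epg"]
        truth = pd.Series(resp["truth"]["delta_epg"][trt],
                          index=sim.scores["subject_id"])
        assert np.abs(recovered - truth).max() < 0.02  # rounding of raw values only


def test_linear_expectation_of_depg_at_max_score():
    cfg = SimConfig()
    assert cfg.epg_mu + cfg.epg_gamma * 10 == pytest.approx(0.0)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(n=0)
    with pytest.raises(ValueError):
        SimConfig(or_ht=-1)
    with pytest.raises(ValueError):
        SimConfig(allele_freqs={"rs4880": 1.5})


def test_null_cohort_disorders_independent_of_score():
    cfg = SimConfig(n=5000, seed=77, or_ht=1.0, or_dl=1.0, or_t2d=1.0, or_vo=1.0)
    sim = simulate_cohort(cfg)
    from lgiob.stats import logistic_or

    high = (sim.scores["stratum"] == "high").to_numpy(float)
    for name, flag in sim.truth["latent_flags"].items():
        res = logistic_or(flag.astype(float), high)
        assert res.ci_low < 1.0 < res.ci_high, name
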