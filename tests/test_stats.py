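"""Association stage: gating, correlations, regression, logistic OR, ROC."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy import stats as sps

from lgiob.stats import (
    SeparationError,
    group_compare,
    linear_model,
    logistic_or,
    normality_gate,
    partial_pearson,
    roc_auc,
    spearman,
    two_way_ancova,
)

rng0 = np.random.default_rng(20240917)


# ---------------------------------------------------------------- gating
def test_gate_normal_sample_parametric():
    x = np.random.default_rng(1).normal(0, 1, 40)
    dec = normality_gate(x)
    assert dec.route == "parametric" and dec.test == "shapiro"


def test_gate_lognormal_goes_log():
    x = np.exp(np.random.default_rng(2).normal(0, 1, 40))
    dec = normality_gate(x)
    assert dec.route == "log_transform"


def test_gate_zeros_block_log():
    x = np.exp(np.random.default_rng(3).normal(0, 1.5, 60))
    x[::7] = 0.0
    dec = normality_gate(x)
    assert dec.route == "nonparametric" and dec.test == "lilliefors"


# ------------------------------------------------------------ correlations
def test_spearman_examples():
    assert spearman([1, 2, 3, 4], [10, 20, 30, 40]).estimate == pytest.approx(1.0)
    assert spearman([1, 2, 3], [3, 1, 2]).estimate == pytest.approx(-0.5)
    assert spearman([1, 2, 3], [-1, -2, -3]).estimate == pytest.approx(-1.0)
    assert "constant_input" in spearman([1, 1, 1], [1, 2, 3]).flags


def test_partial_pearson_reduces_to_pearson():
    x = rng0.normal(size=30)
    y = 0.5 * x + rng0.normal(size=30)
    res = partial_pearson(x, y)
    r_ref, p_ref = sps.pearsonr(x, y)
    assert res.estimate == pytest.approx(r_ref, abs=1e-12)
    assert res.p == pytest.approx(p_ref, rel=1e-9)


def test_orthogonal_covariate_leaves_r_unchanged():
    n = 64
    x = rng0.normal(size=n)
    y = 0.3 * x + rng0.normal(size=n)
    z = rng0.normal(size=n)
    # residualize z against [1, x, y] so it is exactly orthogonal to both
    design = np.column_stack([np.ones(n), x, y])
    z -= design @ np.linalg.lstsq(design, z, rcond=None)[0]
    plain = partial_pearson(x, y).estimate
    adjusted = partial_pearson(x, y, z).estimate
    assert abs(plain - adjusted) < 1e-9


def test_partial_pearson_removes_shared_confounder():
    n = 500
    rng = np.random.default_rng(7)
    age = rng.normal(50, 10, n)
    x = age + rng.normal(0, 5, n)
    y = age + rng.normal(0, 5, n)
    res = partial_pearson(x, y, pd.DataFrame({"age": age}))
    assert abs(res.estimate) < 0.1
    assert sps.pearsonr(x, y)[0] > 0.6  # confounded before adjustment


def test_partial_pearson_matches_pingouin():
    pingouin = pytest.importorskip("pingouin")
    n = 80
    rng = np.random.default_rng(12)
    df = pd.DataFrame({"x": rng.normal(size=n), "z": rng.normal(size=n)})
    df["y"] = 0.4 * df.x + 0.3 * df.z + rng.normal(size=n)
    ref = pingouin.partial_corr(df, x="x", y="y", covar="z")
    res = partial_pearson(df.x, df.y, pd.DataFrame({"z": df.z}))
    assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


def test_partial_pearson_collinear_covariates_error():
    x = rng0.normal(size=20)
    y = rng0.normal(size=20)
    z = rng0.normal(size=20)
    with pytest.raises(ValueError, match="collinear"):
        partial_pearson(x, y, np.column_stack([z, 2 * z]))


# ---------------------------------------------------------------- linear
def test_linear_model_exact_designs():
    x = np.arange(10.0)
    res = linear_model(2 * x, pd.DataFrame({"x": x}))[0]
    assert res.estimate == pytest.approx(2.0, abs=1e-12)
    z = np.array([0, 1, 0, 1, 1, 0, 1, 0, 1, 1], dtype=float)
    both = linear_model(x + z, pd.DataFrame({"x": x, "z": z}))
    assert both[0].estimate == pytest.approx(1.0, abs=1e-9)
    assert both[1].estimate == pytest.approx(1.0, abs=1e-9)


def test_linear_model_names_aliased_column():
    x = np.arange(12.0)
    with pytest.raises(ValueError, match="aliased"):
        linear_model(x, pd.DataFrame({"x1": x, "x2": 2 * x}))


def test_linear_model_recovers_small_slope():
    rng = np.random.default_rng(99)
    score = rng.integers(0, 11, 5000).astype(float)
    y = 0.145 * score + rng.normal(0, 1.0, 5000)
    res = linear_model(y, pd.DataFrame({"score": score}))[0]
    assert res.ci_low <= 0.145 <= res.ci_high


# -------------------------------------------------------------- logistic
def test_logistic_or_closed_form_2x2():
    # exposed: 10 cases / 10 controls; unexposed: 5 / 20 -> OR = ad/bc = 4
    y = np.r_[np.ones(10), np.zeros(10), np.ones(5), np.zeros(20)]
    e = np.r_[np.ones(20), np.zeros(25)]
    res = logistic_or(y, e)
    assert res.estimate == pytest.approx(4.0, abs=1e-8)
    assert res.ci_low < 4.0 < res.ci_high


def test_logistic_or_matches_statsmodels_with_covariates():
    import statsmodels.api as sm

    rng = np.random.default_rng(3)
    n = 400
    e = (rng.random(n) < 0.5).astype(float)
    age = rng.normal(0, 1, n)
    y = (rng.random(n) < sps.norm.cdf(-0.5 + 0.6 * e + 0.3 * age)).astype(float)
    res = logistic_or(y, e, pd.DataFrame({"age": age}))
    X = sm.add_constant(np.column_stack([e, age]))
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.log(res.estimate) == pytest.approx(ref.params[1], abs=1e-6)


def test_logistic_or_detects_separation():
    y = np.r_[np.ones(10), np.zeros(10)]
    e = y.copy()  # all exposed are cases
    with pytest.raises(SeparationError):
        logistic_or(y, e)


def test_logistic_or_null_ci_contains_one():
    rng = np.random.default_rng(21)
    n = 2000
    e = (rng.random(n) < 0.5).astype(float)
    y = (rng.random(n) < 0.3).astype(float)
    res = logistic_or(y, e)
    assert res.ci_low < 1.0 < res.ci_high


# ------------------------------------------------------------------- ROC
def test_roc_auc_examples():
    perfect = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert perfect.auc == 1.0
    mixed = roc_auc([0.9, 0.8, 0.3], [1, 0, 1])
    assert mixed.auc == pytest.approx(0.5)  # one concordant, one discordant pair
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_roc_curve_shape():
    rng = np.random.default_rng(8)
    s = rng.integers(0, 11, 200).astype(float)
    y = (rng.random(200) < 0.3).astype(float)
    res = roc_auc(s, y)
    assert res.fpr[0] == 0.0 and res.fpr[-1] == 1.0
    assert res.tpr[0] == 0.0 and res.tpr[-1] == 1.0
    assert all(b >= a for a, b in zip(res.tpr, res.tpr[1:]))


@settings(max_examples=200, deadline=None, derandomize=True)
@given(hst.data())
def test_roc_auc_equals_mann_whitney(data):
    n1 = data.draw(hst.integers(1, 8))
    n0 = data.draw(hst.integers(1, 8))
    vals = data.draw(hst.lists(hst.integers(0, 5), min_size=n1 + n0, max_size=n1 + n0))
    scores = np.asarray(vals, dtype=float)
    labels = np.r_[np.ones(n1), np.zeros(n0)]
    auc = roc_auc(scores, labels).auc
    u = sps.mannwhitneyu(scores[:n1], scores[n1:], alternative="two-sided").statistic
    assert auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_roc_auc_matches_sklearn():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(17)
    s = rng.normal(size=300) + 0.8 * (rng.random(300) < 0.4)
    y = (rng.random(300) < 0.4).astype(float)
    assert roc_auc(s, y).auc == pytest.approx(roc_auc_score(y, s), abs=1e-12)


def test_roc_auc_null_near_half():
    rng = np.random.default_rng(6)
    s = rng.integers(0, 11, 2000).astype(float)
    y = rng.permutation(np.r_[np.ones(600), np.zeros(1400)])
    assert abs(roc_auc(s, y).auc - 0.5) < 0.03


# ----------------------------------------------------------------- ANOVA
def test_two_way_ancova_main_effect_only():
    rng = np.random.default_rng(31)
    n = 400
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    cov = rng.normal(size=n)
    y = 1.0 * a + 0.2 * cov + rng.normal(size=n)
    out = two_way_ancova(y, a, b, cov)
    assert out["effects"]["A"]["p"] < 1e-6
    assert out["effects"]["AxB"]["p"] > 0.01


def test_two_way_ancova_detects_crossover():
    rng = np.random.default_rng(32)
    n = 400
    a = rng.integers(0, 2, n)
    b = rng.integers(0, 2, n)
    y = 1.5 * (a ^ b) + rng.normal(size=n)  # pure interaction
    out = two_way_ancova(y, a, b, rng.normal(size=n))
    assert out["effects"]["AxB"]["p"] < 1e-6


def test_two_way_ancova_rejects_empty_cell():
    a = np.array([0, 0, 0, 0, 1, 1])
    b = np.array([0, 0, 1, 1, 0, 0])  # cell (1,1) empty
    with pytest.raises(ValueError, match="cell"):
        two_way_ancova(np.arange(6.0), a, b, np.zeros(6))


# --------------------------------------------------------- group compare
def test_group_compare_identical_groups():
    res = group_compare([1, 2, 3], [1, 2, 3], gate=False)
    assert res.estimate == 0 and res.p == pytest.approx(1.0)


def test_group_compare_closed_form_pooled_t():
    res = group_compare([1, 2, 3], [2, 3, 4], gate=False)
    # pooled SD = 1, SE = sqrt(2/3), t = -1 / SE
    assert res.estimate == pytest.approx(-1.0)
    assert res.p == pytest.approx(2 * sps.t.sf(np.sqrt(1.5), 4), rel=1e-9)


def test_group_compare_large_shift():
    rng = np.random.default_rng(41)
    a = rng.normal(0, 1, 30)
    assert group_compare(a, a + 10).p < 1e-10


def test_group_compare_degenerate_variance():
    res = group_compare([2, 2], [2, 2], gate=False)
    assert "degenerate_variance" in res.flags
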