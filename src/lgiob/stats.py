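"""Inferential stage: normality gating, correlations, regression, ROC.

Every result is returned as an :class:`AssociationResult` carrying the
point estimate, a 95% confidence interval, the two-sided p-value, the
analyzed n and the covariate set, so reports can be assembled without
re-deriving anything.  Alpha is 0.05 two-sided throughout and no
multiple-testing correction is applied (analyses are reported singly).

Method choice is data-dependent: :func:`normality_gate` applies
Shapiro-Wilk below n=50 and the Lilliefors-corrected Kolmogorov-Smirnov
test from n=50 up, attempts a log transform on failure, and falls back to
a nonparametric route; the decision is recorded so a report can state which
test produced each number.

The logistic fit is a small iteratively reweighted least squares (IRLS)
implementation (tolerance 1e-8, max 50 iterations) that detects complete
or quasi-separation by divergence of the coefficient norm instead of
silently reporting a huge odds ratio.  The AUC confidence interval uses
DeLong's variance of the placement values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "AssociationResult",
    "RocResult",
    "GateDecision",
    "SeparationError",
    "normality_gate",
    "spearman",
    "partial_pearson",
    "linear_model",
    "logistic_or",
    "roc_auc",
    "two_way_ancova",
    "group_compare",
]

Z975 = sps.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Complete or quasi-separation in a logistic fit."""


@dataclass(frozen=True)
class AssociationResult:
    method: str
    estimate: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    covariates: tuple[str, ...] = ()
    stratum: str | None = None
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n": self.n,
            "covariates": list(self.covariates),
            "stratum": self.stratum,
            "flags": list(self.flags),
        }


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p: float  # H0: AUC = 0.5
    se: float
    n_pos: int
    n_neg: int
    fpr: tuple[float, ...] = field(repr=False, default=())
    tpr: tuple[float, ...] = field(repr=False, default=())

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "se": self.se,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass(frozen=True)
class GateDecision:
    route: str  # parametric | log_transform | nonparametric
    test: str  # shapiro | lilliefors
    p: float
    p_log: float | None = None


def normality_gate(x, alpha: float = 0.05) -> GateDecision:
    """Decide the analysis route for one variable.

    Shapiro-Wilk for n < 50, Lilliefors-corrected Kolmogorov-Smirnov for
    n >= 50 (parameters are estimated from the data, so the plain KS null
    would be anticonservative).  On rejection, a log transform is tried
    (blocked by nonpositive values); if that also fails the route is
    nonparametric.
    """
    from statsmodels.stats.diagnostic import lilliefors

    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 3:
        raise ValueError("normality_gate requires n >= 3")

    def test(v):
        if v.size < 50:
            return "shapiro", float(sps.shapiro(v).pvalue)
        return "lilliefors", float(lilliefors(v, dist="norm")[1])

    name, p = test(x)
    if p >= alpha:
        return GateDecision("parametric", name, p)
    if np.any(x <= 0):
        return GateDecision("nonparametric", name, p)
    _, p_log = test(np.log(x))
    if p_log >= alpha:
        return GateDecision("log_transform", name, p, p_log)
    return GateDecision("nonparametric", name, p, p_log)


def _fisher_ci(r: float, n: int, k: int = 0, factor: float = 1.0) -> tuple[float, float]:
    """Fisher-z CI for a correlation with k covariates partialled out."""
    if n - k - 3 <= 0 or abs(r) >= 1:
        return (float("nan"), float("nan"))
    z = np.arctanh(r)
    se = factor / np.sqrt(n - k - 3)
    return (float(np.tanh(z - Z975 * se)), float(np.tanh(z + Z975 * se)))


def spearman(x, y, stratum: str | None = None) -> AssociationResult:
    """Spearman rank correlation (midrank ties), two-sided p, Fieller CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("spearman requires n >= 3 complete pairs")
    flags: tuple[str, ...] = ()
    if np.all(x == x[0]) or np.all(y == y[0]):
        return AssociationResult("spearman", float("nan"), float("nan"), float("nan"),
                                 float("nan"), n, stratum=stratum, flags=("constant_input",))
    rho, p = sps.spearmanr(x, y)
    lo, hi = _fisher_ci(float(rho), n, factor=1.06)  # Fieller variance inflation for ranks
    return AssociationResult("spearman", float(rho), lo, hi, float(p), n,
                             stratum=stratum, flags=flags)


def _residualize(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(v)), cov]) if cov.size else np.ones((len(v), 1))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates in partial correlation")
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def partial_pearson(x, y, covariates=None, stratum: str | None = None) -> AssociationResult:
    """Pearson correlation of x and y after regressing both on covariates.

    Equivalent to the classical partial correlation; with no covariates it
    reduces exactly to the plain Pearson correlation.  The p-value uses a
    t reference with df = n - 2 - k (k = number of covariates).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov = np.empty((x.size, 0))
        cov_names: tuple[str, ...] = ()
    else:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_names = tuple(
            covariates.columns if isinstance(covariates, pd.DataFrame)
            else (f"c{i}" for i in range(cov.shape[1]))
        )
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(cov).any(axis=1))
    x, y, cov = x[ok], y[ok], cov[ok]
    n = x.size
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("partial_pearson requires n > covariates + 2")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    if denom == 0:
        return AssociationResult("partial_pearson", float("nan"), float("nan"), float("nan"),
                                 float("nan"), n, cov_names, stratum, ("constant_input",))
    r = float((rx * ry).sum() / denom)
    df = n - 2 - k
    t = r * np.sqrt(df / max(1e-300, 1.0 - r**2))
    p = float(2 * sps.t.sf(abs(t), df)) if abs(r) < 1 else 0.0
    lo, hi = _fisher_ci(r, n, k)
    return AssociationResult("partial_pearson" if k else "pearson", r, lo, hi, p, n,
                             cov_names, stratum)


def linear_model(y, predictors: pd.DataFrame, stratum: str | None = None) -> list[AssociationResult]:
    """OLS of y on the predictor frame (intercept added); one result per predictor."""
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = predictors.astype(float)
    ok = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[ok], X.loc[ok]
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        for col in X.columns:
            reduced = design.drop(columns=[col])
            if np.linalg.matrix_rank(reduced.to_numpy()) == rank:
                raise ValueError(f"rank-deficient design: column {col!r} is aliased")
        raise ValueError("rank-deficient design")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    out = []
    for col in X.columns:
        out.append(AssociationResult(
            "linear_regression", float(fit.params[col]),
            float(ci.loc[col, 0]), float(ci.loc[col, 1]),
            float(fit.pvalues[col]), int(fit.nobs),
            tuple(c for c in X.columns if c != col), stratum,
        ))
    return out


def _irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                   max_iter: int = 50, beta_cap: float = 30.0) -> tuple[np.ndarray, np.ndarray]:
    """IRLS logistic fit returning (beta, covariance); raises on separation."""
    n, p = X.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            beta_new = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix in logistic fit") from exc
        if np.max(np.abs(beta_new)) > beta_cap:
            raise SeparationError(
                "logistic coefficients diverging (|beta| > "
                f"{beta_cap}); data are completely or quasi-separated"
            )
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < tol:
            break
    else:
        warnings.warn("IRLS did not converge within 50 iterations", stacklevel=2)
    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    return beta, cov


def logistic_or(outcome, exposure, covariates: pd.DataFrame | None = None,
                stratum: str | None = None) -> AssociationResult:
    """Odds ratio for a binary exposure from a maximum-likelihood logistic fit.

    ``outcome`` and ``exposure`` are binary vectors (exposure 1 = high
    stratum; level 0 is the reference with OR = 1).  The Wald CI is
    computed on the log-odds scale.  Each exposure level must contain at
    least one event and one non-event; violations and fit divergence raise
    :class:`SeparationError` rather than returning a silent huge OR.
    """
    y = np.asarray(outcome, dtype=float)
    e = np.asarray(exposure, dtype=float)
    if covariates is None:
        cov = np.empty((y.size, 0))
        cov_names: tuple[str, ...] = ()
    else:
        cov = covariates.to_numpy(dtype=float)
        cov_names = tuple(covariates.columns)
    ok = ~(np.isnan(y) | np.isnan(e) | np.isnan(cov).any(axis=1))
    y, e, cov = y[ok], e[ok], cov[ok]
    if not set(np.unique(y)) <= {0.0, 1.0} or not set(np.unique(e)) <= {0.0, 1.0}:
        raise ValueError("outcome and exposure must be binary 0/1")
    for level in (0.0, 1.0):
        sub = y[e == level]
        if sub.size == 0 or sub.min() == sub.max():
            raise SeparationError(
                f"exposure level {int(level)} lacks both events and non-events "
                "(complete separation on the exposure)"
            )
    X = np.column_stack([np.ones(y.size), e, cov])
    beta, vcov = _irls_logistic(X, y)
    b, se = beta[1], np.sqrt(vcov[1, 1])
    or_ = float(np.exp(b))
    p = float(2 * sps.norm.sf(abs(b / se)))
    return AssociationResult("logistic_or", or_, float(np.exp(b - Z975 * se)),
                             float(np.exp(b + Z975 * se)), p, int(y.size),
                             cov_names, stratum)


def roc_auc(score, outcome) -> RocResult:
    """ROC AUC by the rank (Mann-Whitney) formulation with midrank ties.

    Variance and CI by DeLong's method on the placement values; p-value for
    H0: AUC = 0.5 from the normal approximation.  Curve points come from the
    empirical ROC (monotone from (0,0) to (1,1)).
    """
    from sklearn.metrics import roc_curve

    s = np.asarray(score, dtype=float)
    y = np.asarray(outcome, dtype=float)
    ok = ~(np.isnan(s) | np.isnan(y))
    s, y = s[ok], y[ok]
    pos, neg = s[y == 1], s[y == 0]
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both outcome classes")
    r_all = sps.rankdata(np.concatenate([pos, neg]))
    r_pos = sps.rankdata(pos)
    r_neg = sps.rankdata(neg)
    auc = float((r_all[:n1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
    v10 = (r_all[:n1] - r_pos) / n0  # placement of each positive among negatives
    v01 = 1.0 - (r_all[n1:] - r_neg) / n1
    var = (v10.var(ddof=1) / n1 if n1 > 1 else 0.0) + (v01.var(ddof=1) / n0 if n0 > 1 else 0.0)
    se = float(np.sqrt(var))
    if se > 0:
        lo, hi = max(0.0, auc - Z975 * se), min(1.0, auc + Z975 * se)
        p = float(2 * sps.norm.sf(abs(auc - 0.5) / se))
    else:
        lo = hi = auc
        p = 1.0 if auc == 0.5 else 0.0
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(auc, lo, hi, p, se, n1, n0, tuple(map(float, fpr)), tuple(map(float, tpr)))


def two_way_ancova(y, factor_a, factor_b, covariate,
                   names: tuple[str, str, str] = ("A", "B", "age")) -> dict:
    """Two-way ANOVA of y on two dichotomous factors with one covariate.

    Type-III tests with sum-to-zero contrasts, mirroring the usual
    "simple effects plus interaction, adjusted" report.  Raises on an empty
    factor cell.
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "A": pd.Categorical(factor_a),
        "B": pd.Categorical(factor_b),
        "cov": np.asarray(covariate, dtype=float),
    }).dropna()
    cells = df.groupby(["A", "B"], observed=False).size()
    if (cells < 2).any():
        bad = cells[cells < 2].index.tolist()
        raise ValueError(f"two_way_ancova needs >=2 observations per cell; sparse cells: {bad}")
    fit = smf.ols("y ~ C(A, Sum) * C(B, Sum) + cov", data=df).fit()
    tbl = anova_lm(fit, typ=3)
    label = {"C(A, Sum)": names[0], "C(B, Sum)": names[1],
             "C(A, Sum):C(B, Sum)": f"{names[0]}x{names[1]}", "cov": names[2]}
    return {
        "n": int(len(df)),
        "effects": {
            label[k]: {"F": float(tbl.loc[k, "F"]), "p": float(tbl.loc[k, "PR(>F)"])}
            for k in label
        },
    }


def group_compare(group_a, group_b, gate: bool = True) -> AssociationResult:
    """Two-group comparison routed through the normality gate.

    Parametric route: Student t (Welch when the Levene test rejects equal
    variances); log route: the same on log values; nonparametric fallback:
    Mann-Whitney U.  The estimate is mean(A) - mean(B) on the original scale.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError("group_compare requires >= 2 observations per group")
    diff = float(a.mean() - b.mean())
    if np.allclose(a.std(), 0) and np.allclose(b.std(), 0):
        p = 1.0 if np.isclose(a.mean(), b.mean()) else 0.0
        return AssociationResult("t_test", diff, diff, diff, p,
                                 int(a.size + b.size), flags=("degenerate_variance",))
    route = "parametric"
    if gate and min(a.size, b.size) >= 3:
        ga, gb = normality_gate(a), normality_gate(b)
        routes = {ga.route, gb.route}
        if "nonparametric" in routes:
            route = "nonparametric"
        elif "log_transform" in routes:
            route = "log_transform"
    if route == "nonparametric":
        u, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        return AssociationResult("mann_whitney", diff, float("nan"), float("nan"),
                                 float(p), int(a.size + b.size))
    xa, xb = (np.log(a), np.log(b)) if route == "log_transform" else (a, b)
    equal_var = float(sps.levene(xa, xb).pvalue) >= 0.05
    res = sps.ttest_ind(xa, xb, equal_var=equal_var)
    lo, hi = res.confidence_interval()
    method = "t_test" if equal_var else "welch_t_test"
    if route == "log_transform":
        method += "_log"
    return AssociationResult(method, diff, float(lo), float(hi), float(res.pvalue),
                             int(a.size + b.size),
                             flags=() if route == "parametric" else (route,))
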