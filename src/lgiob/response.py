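"""PBMC omega-3 response: per-gene expression deltas and the summary statistic.

Peripheral blood mononuclear cells are cultured under a control condition
and under each fatty-acid treatment (DHA, EPA).  Expression of the
pro-inflammatory genes IL6 and TNFA is normalized to the housekeeping gene
RPLP0, each treatment is contrasted against the untreated control of the
same subject, and the two gene deltas are summed into a single overall
response per fatty acid:

    dEPG(treatment) = dIL6 + dTNFA,   d = treated_norm - control_norm

A more negative dEPG means a stronger anti-inflammatory response to the
fatty acid.  Normalization defaults to the linear ratio to RPLP0; a log2
scale is available (it changes delta magnitudes, not signs).

Cytokine concentrations measured in the culture medium are compared
control-vs-treated with a paired Student t-test within a score stratum; a
two-way repeated-measures ANOVA (treatment x stratum) is offered as an
alternative contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PRO_INFLAMMATORY_GENES",
    "HOUSEKEEPING_GENE",
    "CONTROL",
    "TREATMENTS",
    "CytokineContrast",
    "normalize_expression",
    "gene_delta",
    "delta_epg",
    "expression_response",
    "cytokine_contrast",
    "cytokine_anova",
]

PRO_INFLAMMATORY_GENES = ("IL6", "TNFA")
HOUSEKEEPING_GENE = "RPLP0"
CONTROL = "control"
TREATMENTS = ("DHA", "EPA")


def normalize_expression(target_raw, housekeeping_raw, scale: str = "linear"):
    """Normalize raw expression against the housekeeping gene.

    ``linear`` returns target/housekeeping; ``log2`` returns
    log2(target/housekeeping) (requires target > 0).
    """
    target = np.asarray(target_raw, dtype=float)
    hk = np.asarray(housekeeping_raw, dtype=float)
    if np.any(hk[~np.isnan(hk)] <= 0):
        raise ValueError("housekeeping expression must be strictly positive")
    ratio = target / hk
    if scale == "linear":
        return ratio
    if scale == "log2":
        if np.any(ratio[~np.isnan(ratio)] <= 0):
            raise ValueError("log2 scale requires strictly positive target expression")
        return np.log2(ratio)
    raise ValueError(f"unknown scale {scale!r}")


def gene_delta(treated_norm, control_norm):
    """Treatment effect of one gene: treated - control (same scale)."""
    return np.asarray(treated_norm, dtype=float) - np.asarray(control_norm, dtype=float)


def delta_epg(delta_il6, delta_tnfa):
    """Overall pro-inflammatory expression response: sum of the gene deltas.

    NaN in either gene delta leaves the total undetermined (NaN).
    """
    return np.asarray(delta_il6, dtype=float) + np.asarray(delta_tnfa, dtype=float)


def expression_response(expression: pd.DataFrame, scale: str = "linear") -> pd.DataFrame:
    """Per-subject treatment deltas and dEPG from long-format expression data.

    ``expression`` has columns subject_id, treatment, gene, value (raw
    units; RPLP0 rows required for every subject x treatment).  Returns one
    row per subject x fatty-acid treatment with delta_IL6, delta_TNFA and
    delta_epg (NaN where a gene measurement is absent).
    """
    required = {"subject_id", "treatment", "gene", "value"}
    if not required <= set(expression.columns):
        raise ValueError(f"expression frame needs columns {sorted(required)}")
    dup = expression.duplicated(["subject_id", "treatment", "gene"])
    if dup.any():
        raise ValueError("duplicate (subject, treatment, gene) measurements")

    wide = expression.pivot(index=["subject_id", "treatment"], columns="gene", values="value")
    if HOUSEKEEPING_GENE not in wide.columns or wide[HOUSEKEEPING_GENE].isna().any():
        raise ValueError(f"{HOUSEKEEPING_GENE} required for every (subject, treatment)")
    norm = pd.DataFrame(index=wide.index)
    for gene in PRO_INFLAMMATORY_GENES:
        raw = wide[gene] if gene in wide.columns else np.nan
        norm[gene] = normalize_expression(raw, wide[HOUSEKEEPING_GENE], scale=scale)

    rows = []
    for sid, sub in norm.groupby(level="subject_id"):
        sub = sub.droplevel("subject_id")
        if CONTROL not in sub.index:
            raise ValueError(f"subject {sid!r} has no control measurements")
        for trt in TREATMENTS:
            if trt not in sub.index:
                continue
            deltas = {
                gene: float(gene_delta(sub.loc[trt, gene], sub.loc[CONTROL, gene]))
                for gene in PRO_INFLAMMATORY_GENES
            }
            rows.append({
                "subject_id": sid,
                "treatment": trt,
                "delta_IL6": deltas["IL6"],
                "delta_TNFA": deltas["TNFA"],
                "delta_epg": float(delta_epg(deltas["IL6"], deltas["TNFA"])),
            })
    return pd.DataFrame(rows, columns=["subject_id", "treatment",
                                       "delta_IL6", "delta_TNFA", "delta_epg"])


@dataclass(frozen=True)
class CytokineContrast:
    """Paired control-vs-treated contrast of a cytokine concentration."""

    mean_delta: float
    t: float
    p: float
    n_pairs: int
    flags: tuple[str, ...] = ()


def cytokine_contrast(control, treated) -> CytokineContrast:
    """Paired Student t-test of treated vs control concentrations.

    Delta is reported as mean(treated - control).  Requires >= 2 complete
    pairs; zero variance of the differences leaves p undefined and flagged
    (unless the differences are identically zero, where t=0, p=1 by
    convention: no effect, no evidence).
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if control.shape != treated.shape:
        raise ValueError("control and treated must be paired (same length)")
    ok = ~(np.isnan(control) | np.isnan(treated))
    control, treated = control[ok], treated[ok]
    n = control.size
    if n < 2:
        raise ValueError("cytokine_contrast requires at least 2 complete pairs")
    diff = treated - control
    mean_delta = float(diff.mean())
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return CytokineContrast(0.0, 0.0, 1.0, n, ("zero_difference",))
        return CytokineContrast(mean_delta, np.inf * np.sign(mean_delta), float("nan"),
                                n, ("zero_variance",))
    t, p = sps.ttest_rel(treated, control)
    return CytokineContrast(mean_delta, float(t), float(p), n)


def cytokine_anova(cytokines: pd.DataFrame, strata: pd.Series) -> pd.DataFrame:
    """Two-way repeated-measures ANOVA alternative to the paired t contrast.

    ``cytokines`` is long-format (subject_id, treatment, cytokine, value)
    including control rows; ``strata`` maps subject_id -> low/high.  For each
    cytokine and fatty-acid treatment, fits an OLS on the paired differences
    with stratum as the between factor and reports treatment, stratum and
    interaction p-values via an F-test framework on the difference scores
    (mathematically the mixed-design treatment and interaction tests).
    """
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    rows = []
    wide = cytokines.pivot(index=["subject_id", "cytokine"], columns="treatment", values="value")
    for cyt, sub in wide.groupby(level="cytokine"):
        sub = sub.droplevel("cytokine")
        for trt in TREATMENTS:
            if trt not in sub.columns or CONTROL not in sub.columns:
                continue
            d = (sub[trt] - sub[CONTROL]).dropna()
            grp = strata.reindex(d.index)
            df = pd.DataFrame({"diff": d, "stratum": grp}).dropna()
            if df["stratum"].nunique() < 2 or len(df) < 4:
                continue
            fit = smf.ols("diff ~ C(stratum)", data=df).fit()
            tbl = anova_lm(fit, typ=2)
            # Intercept test of the difference scores = within-subject treatment effect.
            icpt = fit.t_test("Intercept")
            rows.append({
                "cytokine": cyt,
                "treatment": trt,
                "p_treatment": float(icpt.pvalue),
                "p_interaction": float(tbl.loc["C(stratum)", "PR(>F)"]),
                "n": int(len(df)),
            })
    return pd.DataFrame(rows)
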