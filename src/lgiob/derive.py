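"""Derived anthropometric/lipid indices and the metabolic-risk classification.

Indices: BMI = weight / height^2 (kg/m^2); mean arterial pressure
MAP = 2/3*DBP + 1/3*SBP (mmHg); waist-to-height ratio WtHR = waist / height
(dimensionless, waist in cm and height in m); LDL cholesterol by the
Friedewald formula LDLc = TC - (HDLc + TG/5) (mg/dL, unreliable above
TG 400 mg/dL); and the TG/HDLc ratio as an insulin-resistance proxy.

Risk classification (per-condition, inclusive thresholds):

* HT   - diagnosis, antihypertensive treatment, SBP >= 130 or DBP >= 80 mmHg
* DL   - diagnosis or lipid-lowering medication
* T2D  - diagnosis or antidiabetic treatment
* VO   - WtHR >= 0.51 (women) / >= 0.53 (men)
* MR   - two or more of the four conditions above

Flags with missing inputs propagate as undetermined (pandas NA, Kleene
three-valued logic) rather than false: "not at risk" requires affirmative
evidence on every branch.  Undetermined flags are excluded from the
alteration count.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "bmi",
    "map_bp",
    "wthr",
    "friedewald_ldl",
    "tg_hdl_ratio",
    "derive_phenotypes",
    "classify_risk",
    "metabolic_risk",
    "OVERWEIGHT_BMI",
    "HT_SBP",
    "HT_DBP",
    "VO_WTHR_FEMALE",
    "VO_WTHR_MALE",
    "FRIEDEWALD_TG_LIMIT",
]

OVERWEIGHT_BMI = 25.0
HT_SBP = 130.0
HT_DBP = 80.0
VO_WTHR_FEMALE = 0.51
VO_WTHR_MALE = 0.53
FRIEDEWALD_TG_LIMIT = 400.0


def bmi(weight, height):
    """Body mass index, kg/m^2: weight / height^2 (weight kg, height m)."""
    height = np.asarray(height, dtype=float)
    if np.any(height[~np.isnan(height)] <= 0):
        raise ValueError("height must be strictly positive")
    return np.asarray(weight, dtype=float) / height**2


def map_bp(sbp, dbp):
    """Mean arterial pressure, mmHg: 2/3*DBP + 1/3*SBP.

    SBP below DBP is physiologically inverted; it is warned about but still
    computed (the formula remains well defined).
    """
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any(sbp < dbp):
            warnings.warn("SBP < DBP for some subjects; MAP computed anyway", stacklevel=2)
    return (2.0 * dbp + sbp) / 3.0


def wthr(waist, height):
    """Waist-to-height ratio (waist cm, height m)."""
    waist = np.asarray(waist, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(waist[~np.isnan(waist)] <= 0) or np.any(height[~np.isnan(height)] <= 0):
        raise ValueError("waist and height must be strictly positive")
    return waist / (height * 100.0)


def friedewald_ldl(tc, hdlc, tg, return_flags: bool = False):
    """Friedewald LDL cholesterol, mg/dL: TC - (HDLc + TG/5).

    With ``return_flags=True`` also returns a boolean array marking values
    that are unreliable: TG above 400 mg/dL (outside the formula's validity
    range) or a negative result.
    """
    tc = np.asarray(tc, dtype=float)
    hdlc = np.asarray(hdlc, dtype=float)
    tg = np.asarray(tg, dtype=float)
    for name, arr in (("TC", tc), ("HDLc", hdlc), ("TG", tg)):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"{name} must be nonnegative")
    ldl = tc - (hdlc + tg / 5.0)
    if return_flags:
        with np.errstate(invalid="ignore"):
            flagged = (tg > FRIEDEWALD_TG_LIMIT) | (ldl < 0)
        return ldl, flagged
    return ldl


def tg_hdl_ratio(tg, hdlc):
    """Triglyceride / HDL-cholesterol ratio (both mg/dL)."""
    tg = np.asarray(tg, dtype=float)
    hdlc = np.asarray(hdlc, dtype=float)
    if np.any(hdlc[~np.isnan(hdlc)] <= 0):
        raise ValueError("HDLc must be strictly positive")
    return tg / hdlc


def derive_phenotypes(phen: pd.DataFrame) -> pd.DataFrame:
    """Add derived index columns to a canonical phenotype frame.

    Adds (where inputs exist): bmi, overweight (BMI >= 25), wthr, map,
    ldlc, ldlc_flagged, tg_hdl.  Missing inputs yield NA outputs.
    """
    out = phen.copy()
    if {"weight", "height"} <= set(out.columns):
        out["bmi"] = bmi(out["weight"], out["height"])
        out["overweight"] = pd.array(out["bmi"] >= OVERWEIGHT_BMI, dtype="boolean")
        out.loc[out["bmi"].isna(), "overweight"] = pd.NA
    if {"waist", "height"} <= set(out.columns):
        out["wthr"] = wthr(out["waist"], out["height"])
    if {"sbp", "dbp"} <= set(out.columns):
        out["map"] = map_bp(out["sbp"], out["dbp"])
    if {"tc", "hdlc", "tg"} <= set(out.columns):
        ldl, flagged = friedewald_ldl(out["tc"], out["hdlc"], out["tg"], return_flags=True)
        out["ldlc"] = ldl
        out["ldlc_flagged"] = flagged
    if {"tg", "hdlc"} <= set(out.columns):
        out["tg_hdl"] = tg_hdl_ratio(out["tg"], out["hdlc"])
    return out


def _kleene_any(frame: pd.DataFrame) -> pd.Series:
    """Row-wise three-valued OR across nullable-boolean columns."""
    acc = pd.Series(pd.array([False] * len(frame), dtype="boolean"), index=frame.index)
    for col in frame.columns:
        acc = acc | frame[col].astype("boolean")
    return acc


def classify_risk(derived: pd.DataFrame) -> pd.DataFrame:
    """Apply the per-condition risk rules to a derived phenotype frame.

    Expects the canonical columns plus ``wthr`` (call
    :func:`derive_phenotypes` first).  Returns a frame with nullable-boolean
    HT/DL/T2D/VO plus n_alterations and MR (see :func:`metabolic_risk`).
    Sex missing where VO is computable leaves VO undetermined with a warning.
    """
    n = len(derived)
    idx = derived.index

    def col(name) -> pd.Series:
        if name in derived.columns:
            return derived[name]
        return pd.Series([pd.NA] * n, index=idx)

    def num_flag(series, cut) -> pd.Series:
        vals = pd.to_numeric(pd.Series(series, index=idx), errors="coerce").to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            s = pd.array(vals >= cut, dtype="boolean")
        s[np.isnan(vals)] = pd.NA
        return pd.Series(s, index=idx)

    ht = _kleene_any(pd.DataFrame({
        "dx": col("ht_dx"),
        "med": col("antihypertensive_med"),
        "sbp": num_flag(col("sbp"), HT_SBP),
        "dbp": num_flag(col("dbp"), HT_DBP),
    }))
    dl = _kleene_any(pd.DataFrame({"dx": col("dl_dx"), "med": col("lipid_lowering_med")}))
    t2d = _kleene_any(pd.DataFrame({"dx": col("t2d_dx"), "med": col("antidiabetic_med")}))

    sex = col("sex").astype("string").str.lower() if "sex" in derived.columns else col("sex")
    wthr_vals = pd.to_numeric(col("wthr"), errors="coerce")
    cuts = pd.Series(np.full(n, np.nan), index=idx)
    cuts[sex == "female"] = VO_WTHR_FEMALE
    cuts[sex == "male"] = VO_WTHR_MALE
    with np.errstate(invalid="ignore"):
        vo_arr = pd.array(
            wthr_vals.to_numpy(dtype=float) >= cuts.to_numpy(dtype=float), dtype="boolean"
        )
    vo = pd.Series(vo_arr, index=idx)
    vo[wthr_vals.isna().to_numpy() | cuts.isna().to_numpy()] = pd.NA
    if (wthr_vals.notna() & cuts.isna()).any():
        warnings.warn("sex missing for some subjects with WtHR; VO left undetermined",
                      stacklevel=2)

    flags = pd.DataFrame({"HT": ht, "DL": dl, "T2D": t2d, "VO": vo}, index=idx)
    return metabolic_risk(flags)


def metabolic_risk(flags: pd.DataFrame) -> pd.DataFrame:
    """Fill n_alterations and MR from the four condition flags.

    n_alterations counts determinate True flags (undetermined flags are
    excluded with a warning); MR = n_alterations >= 2, undetermined only
    when all four flags are undetermined.
    """
    out = flags.copy()
    four = out[["HT", "DL", "T2D", "VO"]]
    if four.isna().to_numpy().any():
        warnings.warn("undetermined risk flags excluded from the alteration count",
                      stacklevel=2)
    count = four.fillna(False).astype(bool).sum(axis=1).astype(int)
    out["n_alterations"] = count
    mr = pd.Series(pd.array(count >= 2, dtype="boolean"), index=out.index)
    mr[four.isna().all(axis=1)] = pd.NA
    out["MR"] = mr
    return out
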