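"""End-to-end run: score -> derive -> classify -> associate -> report.

One :func:`run_pipeline` call reproduces the full analysis sequence on
either real input files or a simulated cohort, and emits a reproducible
report bundle (TSV tables + one JSON report).  Because the method choice
in the association stage is data-dependent (normality gating), every
analysis appends an entry to an explicit analysis ledger naming the method
used, the covariate set and the analyzed n; analyses whose input variables
are missing are skipped with a recorded reason and the run continues.

Confounder presets for the logistic odds ratios:

* ``methods`` (default): age, sex, overweight and ethnicity, with
  overweight automatically excluded for the visceral-obesity outcome;
* ``figure4``: age, sex and ethnicity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cio
from . import derive as dv
from . import response as resp
from . import stats as st
from .panel import SnpPanel, default_panel
from .score import DEFAULT_THRESHOLD, median_threshold, score_summary, score_table
from .simulate import SimConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "sensitivity_drop_snp", "CONFOUNDER_PRESETS"]

CONFOUNDER_PRESETS = {
    "methods": ("age", "male", "overweight", "ethnicity"),
    "figure4": ("age", "male", "ethnicity"),
}

OUTCOMES = ("HT", "DL", "T2D", "VO", "MR")


@dataclass
class RunConfig:
    """Inputs and policies of one pipeline run.

    Exactly one of (``genotypes``) and (``simulate``) must be given; real
    inputs are paths in the formats :mod:`lgiob.cohort` reads.
    """

    genotypes: str | Path | None = None
    genotypes_format: str = "table"  # table | vcf
    phenotypes: str | Path | None = None
    expression: str | Path | None = None
    cytokines: str | Path | None = None
    simulate: SimConfig | None = None
    panel: SnpPanel = field(default_factory=default_panel)
    threshold: int | str = DEFAULT_THRESHOLD  # integer or "median"
    confounders: str = "methods"
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self):
        real = self.genotypes is not None
        if real == (self.simulate is not None):
            raise ValueError("exactly one of real inputs (genotypes) or simulate mode required")
        if self.confounders not in CONFOUNDER_PRESETS:
            raise ValueError(f"confounders must be one of {sorted(CONFOUNDER_PRESETS)}")


def _load_inputs(cfg: RunConfig):
    """Produce (cohort, scores, expression_df, cytokines_df) for either mode."""
    if cfg.simulate is not None:
        sim = simulate_cohort(cfg.simulate, cfg.panel, with_expression=True)
        tables = sim.truth.get("_expression_tables", {})
        return sim.cohort, tables.get("expression"), tables.get("cytokines")
    reader = cio.read_vcf_genotypes if cfg.genotypes_format == "vcf" else cio.read_genotype_table
    genotypes = reader(cfg.genotypes, cfg.panel)
    if cfg.phenotypes is not None:
        phen = cio.read_phenotypes(cfg.phenotypes)
    else:
        phen = pd.DataFrame({"subject_id": [g.subject_id for g in genotypes]})
    cohort = cio.join_cohort(genotypes, phen, policy="complete_case", panel=cfg.panel,
                             provenance={"genotypes": str(cfg.genotypes),
                                         "phenotypes": str(cfg.phenotypes)})
    expression = pd.read_csv(cfg.expression) if cfg.expression else None
    cytokines = pd.read_csv(cfg.cytokines) if cfg.cytokines else None
    return cohort, expression, cytokines


def _ethnicity_dummies(phen: pd.DataFrame, min_count: int = 10) -> pd.DataFrame:
    """One-hot ethnicity covariates, collapsing rare levels into the modal one.

    Levels with fewer than ``min_count`` subjects are merged into the most
    common category to avoid quasi-separation on a nuisance covariate.
    """
    eth = phen["ethnicity"].astype("string")
    counts = eth.value_counts()
    if len(counts) == 0:
        return pd.DataFrame(index=phen.index)
    modal = counts.index[0]
    rare = counts[counts < min_count].index
    eth = eth.where(~eth.isin(rare), modal)
    dummies = pd.get_dummies(eth, prefix="eth", drop_first=True)
    return dummies.astype(float)


def _covariate_frame(phen: pd.DataFrame, derived: pd.DataFrame, preset: tuple[str, ...],
                     exclude: tuple[str, ...] = ()) -> pd.DataFrame | None:
    cols = {}
    for name in preset:
        if name in exclude:
            continue
        if name == "age" and "age" in phen:
            cols["age"] = phen["age"].astype(float)
        elif name == "male" and "sex" in phen:
            cols["male"] = (phen["sex"] == "male").astype(float)
        elif name == "overweight" and "overweight" in derived:
            cols["overweight"] = derived["overweight"].astype("float")
        elif name == "ethnicity" and "ethnicity" in phen:
            eth = _ethnicity_dummies(phen)
            for c in eth.columns:
                cols[c] = eth[c]
    if not cols:
        return None
    return pd.DataFrame(cols)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis and return (and optionally write) the report."""
    ledger: list[dict] = []
    report: dict = {"config": {
        "mode": "simulate" if cfg.simulate is not None else "real",
        "panel": cfg.panel.name, "panel_version": cfg.panel.version,
        "confounders": cfg.confounders, "seed": cfg.seed,
    }, "analysis_ledger": ledger}

    cohort, expression, cytokines = _load_inputs(cfg)
    phen = cohort.phenotypes
    report["provenance"] = _jsonable(cohort.provenance)

    # ----- 1. scores -------------------------------------------------------
    threshold = cfg.threshold
    scores_provisional = score_table(cohort.genotypes, cfg.panel, DEFAULT_THRESHOLD)
    if threshold == "median":
        threshold = median_threshold(scores_provisional["score"].dropna().astype(int))
    threshold = int(threshold)
    scores = score_table(cohort.genotypes, cfg.panel, threshold)
    report["config"]["threshold"] = threshold
    scorable = scores["score"].notna()
    report["scores"] = {
        "summary": score_summary(scores.loc[scorable, "score"].astype(int)),
        "n_unscorable": int((~scorable).sum()),
    }
    ledger.append({"analysis": "score", "n": int(scorable.sum()),
                   "threshold": threshold, "panel": cfg.panel.name})

    high = scores["stratum"] == "high"
    score_vals = scores["score"].astype("float").to_numpy()

    # ----- 2. derived phenotypes + risk profiles ---------------------------
    derived = dv.derive_phenotypes(phen)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        risk = dv.classify_risk(derived)
    derived = pd.concat([derived, risk], axis=1)
    report["risk_prevalence"] = {
        c: float(risk[c].astype("boolean").mean(skipna=True))
        if risk[c].notna().any() else None
        for c in ("HT", "DL", "T2D", "VO", "MR")
    }

    # ----- 3. prevalence of 0-4 alterations by stratum ---------------------
    det = risk[["HT", "DL", "T2D", "VO"]].notna().any(axis=1) & scorable
    if det.any():
        tab = (pd.crosstab(risk.loc[det, "n_alterations"], scores.loc[det, "stratum"],
                           normalize="columns")
               .reindex(range(5), fill_value=0.0))
        report["alterations_by_stratum"] = {
            str(col): {str(i): float(tab.loc[i, col]) for i in tab.index}
            for col in tab.columns
        }
        ledger.append({"analysis": "alterations_by_stratum", "n": int(det.sum())})
    else:
        ledger.append({"analysis": "alterations_by_stratum", "skipped": "no determinable flags"})

    # linear regression: alteration count on score, adjusted
    lin_covs = _covariate_frame(phen, derived, CONFOUNDER_PRESETS[cfg.confounders])
    if det.any() and lin_covs is not None:
        X = pd.concat([pd.Series(score_vals, name="score", index=phen.index), lin_covs], axis=1)
        try:
            results = st.linear_model(risk["n_alterations"].to_numpy(dtype=float), X)
            beta = results[0]  # the score coefficient
            report["alteration_regression"] = beta.to_dict()
            ledger.append({"analysis": "alteration_regression", "method": "linear_regression",
                           "covariates": list(X.columns[1:]), "n": beta.n})
        except ValueError as exc:
            ledger.append({"analysis": "alteration_regression", "skipped": str(exc)})

    # ----- 4. OR table ----------------------------------------------------
    or_table: dict[str, dict] = {}
    for outcome in OUTCOMES:
        if outcome not in risk.columns or risk[outcome].isna().all():
            ledger.append({"analysis": f"or_{outcome}", "skipped": "outcome undetermined"})
            continue
        exclude = ("overweight",) if outcome == "VO" else ()
        covframe = _covariate_frame(phen, derived, CONFOUNDER_PRESETS[cfg.confounders], exclude)
        mask = risk[outcome].notna() & scorable
        if covframe is not None:
            mask &= covframe.notna().all(axis=1)
        try:
            res = st.logistic_or(
                risk.loc[mask, outcome].astype(bool).astype(float).to_numpy(),
                high.loc[mask].astype(float).to_numpy(),
                covframe.loc[mask] if covframe is not None else None,
            )
            or_table[outcome] = res.to_dict()
            ledger.append({"analysis": f"or_{outcome}", "method": "logistic_or",
                           "covariates": list(res.covariates), "n": res.n})
        except (st.SeparationError, ValueError) as exc:
            ledger.append({"analysis": f"or_{outcome}", "skipped": str(exc)})
    report["odds_ratios"] = or_table

    # ----- 5. ROC for MR, with and without FTO -----------------------------
    if "MR" in risk.columns and risk["MR"].notna().any():
        mask = risk["MR"].notna() & scorable
        try:
            roc = st.roc_auc(score_vals[mask.to_numpy()],
                             risk.loc[mask, "MR"].astype(bool).astype(float).to_numpy())
            report["roc_mr"] = roc.to_dict()
            report["roc_mr"]["curve"] = {"fpr": list(roc.fpr), "tpr": list(roc.tpr)}
            ledger.append({"analysis": "roc_mr", "method": "roc_auc_delong", "n": roc.n_pos + roc.n_neg})
            if "rs9939609" in cfg.panel:
                report["roc_mr_without_fto"] = _reduced_roc(cfg, cohort, risk, mask, "rs9939609")
                report["roc_mr_without_fto"]["delta_auc"] = (
                    report["roc_mr_without_fto"]["auc"] - roc.auc)
        except ValueError as exc:
            ledger.append({"analysis": "roc_mr", "skipped": str(exc)})
    else:
        ledger.append({"analysis": "roc_mr", "skipped": "MR undetermined for all subjects"})

    # ----- 6. correlation panel -------------------------------------------
    corr: dict[str, dict] = {}
    for marker, col in (("crp", "crp"), ("tg_hdl", "tg_hdl")):
        if col not in derived.columns or derived[col].isna().all():
            ledger.append({"analysis": f"corr_{marker}", "skipped": f"{col} unavailable"})
            continue
        vals = derived[col].astype(float).to_numpy()
        entry: dict[str, dict] = {}
        mask = ~np.isnan(vals) & scorable.to_numpy()
        if mask.sum() >= 3:
            entry["overall_spearman"] = st.spearman(score_vals[mask], vals[mask]).to_dict()
        strata_masks = {}
        if "overweight" in derived.columns:
            owcol = derived["overweight"].astype("boolean")
            strata_masks = {"NW": (~owcol).fillna(False).to_numpy(),
                            "OW_OB": owcol.fillna(False).to_numpy()}
        for name, smask in strata_masks.items():
            m = mask & smask & phen["age"].notna().to_numpy()
            if m.sum() > 3:
                res = st.partial_pearson(score_vals[m], vals[m],
                                         phen.loc[m, ["age"]], stratum=name)
                entry[f"{name}_age_adjusted"] = res.to_dict()
        corr[marker] = entry
        ledger.append({"analysis": f"corr_{marker}",
                       "method": "spearman + age-adjusted partial pearson",
                       "n": int(mask.sum())})
    report["correlations"] = corr

    # ----- 7. omega-3 response ---------------------------------------------
    if expression is not None:
        epg = resp.expression_response(expression)
        strata = scores.set_index("subject_id")["stratum"]
        epg["stratum"] = epg["subject_id"].map(strata)
        epg["score"] = epg["subject_id"].map(scores.set_index("subject_id")["score"].astype("float"))
        epg_report: dict[str, dict] = {}
        for trt, sub in epg.groupby("treatment"):
            entry = {}
            ok = sub["delta_epg"].notna() & sub["score"].notna()
            if ok.sum() >= 3:
                entry["score_correlation"] = st.partial_pearson(
                    sub.loc[ok, "score"], sub.loc[ok, "delta_epg"]).to_dict()
            for stratum, ss in sub[ok].groupby("stratum"):
                if len(ss) >= 3:
                    entry[f"score_correlation_{stratum}"] = st.partial_pearson(
                        ss["score"], ss["delta_epg"], stratum=stratum).to_dict()
            epg_report[trt] = entry
        report["delta_epg"] = epg_report
        ledger.append({"analysis": "delta_epg", "method": "pearson",
                       "n": int(epg["subject_id"].nunique())})
        if cytokines is not None:
            cyt_report: dict[str, dict] = {}
            wide = cytokines.pivot(index=["subject_id", "cytokine"],
                                   columns="treatment", values="value")
            for stratum_name in ("low", "high"):
                sids = strata[strata == stratum_name].index
                for cyt in ("IL6", "TNFA"):
                    try:
                        sub = wide.xs(cyt, level="cytokine").reindex(sids).dropna()
                    except KeyError:
                        continue
                    for trt in resp.TREATMENTS:
                        if trt not in sub.columns or len(sub) < 2:
                            continue
                        c = resp.cytokine_contrast(sub["control"], sub[trt])
                        cyt_report[f"{stratum_name}/{cyt}/{trt}"] = {
                            "mean_delta": c.mean_delta, "t": c.t, "p": c.p,
                            "n_pairs": c.n_pairs, "flags": list(c.flags),
                            "method": "paired_t",
                        }
            report["cytokine_contrasts"] = cyt_report
            ledger.append({"analysis": "cytokine_contrasts", "method": "paired_t"})
    else:
        ledger.append({"analysis": "delta_epg", "skipped": "no expression data"})

    if cfg.out_dir is not None:
        _write_bundle(cfg, report, scores, derived)
    return report


def _reduced_roc(cfg: RunConfig, cohort, risk, mask, rsid: str) -> dict:
    reduced = cfg.panel.drop(rsid)
    rscores = score_table(cohort.genotypes, reduced, DEFAULT_THRESHOLD)
    vals = rscores["score"].astype("float").to_numpy()
    roc = st.roc_auc(vals[mask.to_numpy()],
                     risk.loc[mask, "MR"].astype(bool).astype(float).to_numpy())
    out = roc.to_dict()
    out["panel"] = reduced.name
    out["max_score"] = reduced.max_score
    return out


def sensitivity_drop_snp(cfg: RunConfig, rsid: str) -> dict:
    """Recompute the MR ROC with one SNP removed, on the same cohort.

    Returns the base report plus the reduced-panel AUC and the AUC change.
    The cohort is loaded (or re-simulated with the identical seed) once, so
    only the panel differs between the two ROC computations.
    """
    if rsid not in cfg.panel:
        raise ValueError(f"rsID {rsid!r} not in panel")
    base = run_pipeline(cfg)
    cohort, _, _ = _load_inputs(cfg)
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        risk = dv.classify_risk(dv.derive_phenotypes(cohort.phenotypes))
    scores = score_table(cohort.genotypes, cfg.panel, DEFAULT_THRESHOLD)
    mask = risk["MR"].notna() & scores["score"].notna()
    out = {"base": base, "dropped": rsid}
    if mask.any() and "roc_mr" in base:
        reduced = _reduced_roc(cfg, cohort, risk, mask, rsid)
        out["reduced_roc"] = reduced
        out["delta_auc"] = reduced["auc"] - base["roc_mr"]["auc"]
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_bundle(cfg: RunConfig, report: dict, scores: pd.DataFrame,
                  derived: pd.DataFrame) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores.to_csv(out / "scores.tsv", sep="\t", index=False, na_rep="NA")
    derived.to_csv(out / "derived.tsv", sep="\t", index=False, na_rep="NA")
    rows = []
    for outcome, entry in report.get("odds_ratios", {}).items():
        rows.append({"outcome": outcome, **{k: v for k, v in entry.items()
                                            if k != "covariates"},
                     "covariates": ";".join(entry["covariates"])})
    if rows:
        pd.DataFrame(rows).to_csv(out / "odds_ratios.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
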