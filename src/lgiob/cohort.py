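"""Reading, validating and joining genotype and phenotype data.

Two genotype interfaces are supported and interchangeable: a plain
tab/comma-separated table (one row per subject, one column per rsID, cells
like ``GA``) and VCF 4.x (rsIDs in the ID column, FORMAT/GT).  Genotypes
are validated against the panel's declared allele sets and normalized to
unordered calls.  No strand flipping is ever attempted: rs9939609 is a T/A
(strand-ambiguous) site, so allele labels must match the panel exactly or
the parse fails loudly.

Phenotypes travel as a CSV with canonical column names and units::

    subject_id, age [years], sex {female,male}, ethnicity,
    height [m], weight [kg], waist [cm], hip [cm],
    sbp [mmHg], dbp [mmHg],
    glucose, tc, hdlc, tg [mg/dL], crp [ng/mL],
    ht_dx, dl_dx, t2d_dx,
    antihypertensive_med, lipid_lowering_med, antidiabetic_med  {0,1,NA}
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import pysam

from .panel import Genotype, PanelError, SnpPanel, normalize_genotype

__all__ = [
    "GenotypeRecord",
    "Cohort",
    "GenotypeParseError",
    "MISSING_TOKENS",
    "MISSING_OUT",
    "read_genotype_table",
    "write_genotype_table",
    "read_vcf_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "join_cohort",
    "PHENOTYPE_COLUMNS",
]

#: Tokens accepted as "missing genotype" on input.
MISSING_TOKENS = frozenset({"", "NA", "./.", "--"})
#: Single canonical missing token on output.
MISSING_OUT = "NA"

NUMERIC_PHENOTYPES = (
    "age", "height", "weight", "waist", "hip", "sbp", "dbp",
    "glucose", "tc", "hdlc", "tg", "crp",
)
FLAG_PHENOTYPES = (
    "ht_dx", "dl_dx", "t2d_dx",
    "antihypertensive_med", "lipid_lowering_med", "antidiabetic_med",
)
PHENOTYPE_COLUMNS = ("subject_id", *NUMERIC_PHENOTYPES[:1], "sex", "ethnicity",
                     *NUMERIC_PHENOTYPES[1:], *FLAG_PHENOTYPES)


class GenotypeParseError(ValueError):
    """Genotype input inconsistent with the panel (column or record level)."""


@dataclass(frozen=True)
class GenotypeRecord:
    """Genotype calls of one subject: rsID -> normalized allele pair or None."""

    subject_id: str
    calls: dict[str, Genotype | None]


@dataclass
class Cohort:
    """Joined genotype + phenotype data with provenance.

    ``genotypes`` maps subjects to records; ``phenotypes`` is the canonical
    phenotype frame indexed like ``subject_ids``.  ``provenance`` records
    source files, panel identity, the join policy and how many subjects the
    complete-case filter dropped.
    """

    genotypes: list[GenotypeRecord]
    phenotypes: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def subject_ids(self) -> list[str]:
        return [g.subject_id for g in self.genotypes]

    @property
    def n(self) -> int:
        return len(self.genotypes)


def _parse_cell(cell: str, rsid: str, subject: str, panel: SnpPanel) -> Genotype | None:
    cell = cell.strip()
    if cell in MISSING_TOKENS:
        return None
    snp = panel.get(rsid)
    try:
        g = normalize_genotype(cell)
    except PanelError as exc:
        raise GenotypeParseError(f"subject {subject!r}, {rsid}: {exc}") from exc
    if not set(g) <= snp.alleles:
        raise GenotypeParseError(
            f"subject {subject!r}, {rsid}: alleles {set(g)} not in panel set {set(snp.alleles)}"
        )
    return g


def _sniff_delimiter(path) -> str:
    with open(path, newline="") as fh:
        head = fh.readline()
    return "\t" if head.count("\t") >= head.count(",") else ","


def read_genotype_table(path, panel: SnpPanel) -> list[GenotypeRecord]:
    """Read a TSV/CSV genotype table (rows = subjects, columns = rsIDs)."""
    delim = _sniff_delimiter(path)
    records: list[GenotypeRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        header = [c for c in (reader.fieldnames or []) if c != "subject_id"]
        unknown = [c for c in header if c not in panel]
        if unknown:
            raise GenotypeParseError(f"unknown rsID column(s): {unknown}")
        if "subject_id" not in (reader.fieldnames or []):
            raise GenotypeParseError("genotype table must have a 'subject_id' column")
        for row in reader:
            sid = row["subject_id"]
            calls = {rsid: _parse_cell(row[rsid], rsid, sid, panel) for rsid in header}
            records.append(GenotypeRecord(sid, calls))
    return records


def write_genotype_table(records: Iterable[GenotypeRecord], path, panel: SnpPanel) -> None:
    """Write records as TSV using the panel's display spelling of genotypes."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject_id", *panel.rsids])
        for rec in records:
            row = [rec.subject_id]
            for snp in panel:
                call = rec.calls.get(snp.rsid)
                if call is None:
                    row.append(MISSING_OUT)
                else:
                    row.append(snp.display.get(call, "".join(call)))
            writer.writerow(row)


def read_vcf_genotypes(path, panel: SnpPanel) -> list[GenotypeRecord]:
    """Read panel genotypes from a VCF (plain or bgzipped).

    GT indices are resolved through REF/ALT into nucleotide pairs.  Sites
    whose REF/ALT alleles fall outside the panel's declared alleles are an
    error (never silently strand-flipped); half-missing GT is missing.
    """
    vcf = pysam.VariantFile(str(path))
    samples = list(vcf.header.samples)
    calls: dict[str, dict[str, Genotype | None]] = {s: {} for s in samples}
    for rec in vcf:
        rsid = rec.id
        if rsid is None or rsid not in panel:
            continue
        snp = panel.get(rsid)
        site_alleles = [a for a in rec.alleles if a is not None]
        if any(len(a) != 1 for a in site_alleles) or not set(site_alleles) <= snp.alleles:
            raise GenotypeParseError(
                f"{rsid}: VCF REF/ALT {site_alleles} incompatible with panel alleles "
                f"{sorted(snp.alleles)} (strand flips are never applied)"
            )
        for s in samples:
            gt = rec.samples[s].get("GT")
            if gt is None or len(gt) != 2 or any(i is None for i in gt):
                calls[s][rsid] = None
            else:
                pair = tuple(rec.alleles[i] for i in gt)
                calls[s][rsid] = normalize_genotype(pair)
    vcf.close()
    return [GenotypeRecord(s, calls[s]) for s in samples]


def read_phenotypes(path) -> pd.DataFrame:
    """Read the canonical phenotype CSV and validate it.

    Physical quantities must be strictly positive where present; sex is
    restricted to {female, male}; diagnosis/medication flags come in as
    {0,1,NA} and are stored as nullable booleans.
    """
    df = pd.read_csv(path, dtype={"subject_id": str})
    if "subject_id" not in df.columns:
        raise ValueError("phenotype table must have a 'subject_id' column")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in phenotypes: {dupes}")
    for col in NUMERIC_PHENOTYPES:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            bad = df[col].notna() & (df[col] <= 0)
            if bad.any():
                raise ValueError(
                    f"nonpositive values in {col!r} for subjects "
                    f"{df.loc[bad, 'subject_id'].tolist()}"
                )
    if "sex" in df.columns:
        sex = df["sex"].astype("string").str.lower()
        ok = sex.isna() | sex.isin(["female", "male"])
        if not ok.all():
            raise ValueError(f"sex must be female/male, got {df.loc[~ok, 'sex'].tolist()}")
        df["sex"] = sex
    for col in FLAG_PHENOTYPES:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64").astype("boolean")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in FLAG_PHENOTYPES:
        if col in out.columns:
            out[col] = out[col].astype("Int64")
    out.to_csv(path, index=False, na_rep="NA")


def join_cohort(
    genotypes: Sequence[GenotypeRecord],
    phenotypes: pd.DataFrame,
    policy: Literal["complete_case", "keep_all"] = "complete_case",
    panel: SnpPanel | None = None,
    required_phenotypes: Sequence[str] = (),
    provenance: dict | None = None,
) -> Cohort:
    """Join genotype and phenotype data on subject_id.

    Under ``complete_case`` (the default), subjects missing any panel
    genotype, any ``required_phenotypes`` value, or either side of the join
    are dropped and counted in the provenance.  ``keep_all`` retains the
    union with missing markers intact.
    """
    sids = [g.subject_id for g in genotypes]
    if len(set(sids)) != len(sids):
        dupes = sorted({s for s in sids if sids.count(s) > 1})
        raise ValueError(f"duplicate subject_id in genotypes: {dupes}")
    if phenotypes["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in phenotypes")

    geno_by_id = {g.subject_id: g for g in genotypes}
    phen = phenotypes.set_index("subject_id", drop=False)
    prov = dict(provenance or {})
    prov.update(policy=policy, n_genotyped=len(genotypes), n_phenotyped=len(phen))
    if panel is not None:
        prov.update(panel=panel.name, panel_version=panel.version)

    if policy == "keep_all":
        all_ids = list(dict.fromkeys([*sids, *phen.index]))
        records = [geno_by_id.get(s, GenotypeRecord(s, {})) for s in all_ids]
        phen_out = phen.reindex(all_ids)
        phen_out["subject_id"] = all_ids
        prov["n_final"] = len(all_ids)
        return Cohort(records, phen_out.reset_index(drop=True), prov)

    if policy != "complete_case":
        raise ValueError(f"unknown join policy {policy!r}")

    keep: list[str] = []
    dropped: dict[str, int] = {"no_phenotype": 0, "no_genotype_record": 0,
                               "missing_genotype": 0, "missing_phenotype": 0}
    rsids = panel.rsids if panel is not None else ()
    for sid in sids:
        if sid not in phen.index:
            dropped["no_phenotype"] += 1
            continue
        rec = geno_by_id[sid]
        if any(rec.calls.get(r) is None for r in rsids):
            dropped["missing_genotype"] += 1
            continue
        row = phen.loc[sid]
        if any((col not in phen.columns) or pd.isna(row[col]) for col in required_phenotypes):
            dropped["missing_phenotype"] += 1
            continue
        keep.append(sid)
    dropped["no_genotype_record"] = int((~phen.index.isin(sids)).sum())
    prov["dropped"] = dropped
    prov["n_final"] = len(keep)
    records = [geno_by_id[s] for s in keep]
    phen_out = phen.loc[keep].reset_index(drop=True)
    return Cohort(records, phen_out, prov)
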