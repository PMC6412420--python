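"""Genotype/phenotype IO: parsing, validation, round-trips, joins."""

import numpy as np
import pandas as pd
import pytest

from lgiob.cohort import (
    GenotypeParseError,
    GenotypeRecord,
    join_cohort,
    read_genotype_table,
    read_phenotypes,
    read_vcf_genotypes,
    write_genotype_table,
)
from lgiob.simulate import SimConfig, simulate_genotypes

RSID_ORDER = ("rs1800629", "rs5082", "rs4880", "rs1260326", "rs9939609")

VCF_HEADER = """\
##fileformat=VCFv4.2
##contig=<ID=1>
##contig=<ID=2>
##contig=<ID=6>
##contig=<ID=16>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_table(path, rows, header=("subject_id", *RSID_ORDER)):
    path.write_text("\n".join(["\t".join(header)] + ["\t".join(r) for r in rows]) + "\n")


def test_table_parse_and_unordered_normalization(tmp_path, panel):
    p = tmp_path / "g.tsv"
    write_table(p, [
        ("A", "GA", "TC", "CT", "CC", "TA"),
        ("B", "AG", "CT", "TC", "CC", "AT"),  # swapped spelling, same calls
        ("C", "NA", "", "./.", "--", "TT"),
    ])
    recs = read_genotype_table(p, panel)
    assert recs[0].calls == recs[1].calls
    assert recs[0].calls["rs1800629"] == ("A", "G")
    assert all(recs[2].calls[r] is None for r in RSID_ORDER[:4])
    assert recs[2].calls["rs9939609"] == ("T", "T")


def test_table_rejects_foreign_allele_and_unknown_column(tmp_path, panel):
    p = tmp_path / "bad.tsv"
    write_table(p, [("A", "GT", "CC", "CC", "CC", "TT")])
    with pytest.raises(GenotypeParseError, match="rs1800629"):
        read_genotype_table(p, panel)
    p2 = tmp_path / "col.tsv"
    write_table(p2, [("A", "GG")], header=("subject_id", "rs0000"))
    with pytest.raises(GenotypeParseError, match="rs0000"):
        read_genotype_table(p2, panel)


def test_genotype_table_round_trip(tmp_path, panel):
    records = simulate_genotypes(SimConfig(n=40, seed=7), panel)
    records[3].calls["rs4880"] = None
    out = tmp_path / "rt.tsv"
    write_genotype_table(records, out, panel)
    back = read_genotype_table(out, panel)
    assert [r.calls for r in back] == [r.calls for r in records]
    assert [r.subject_id for r in back] == [r.subject_id for r in records]


def test_vcf_gt_resolution(tmp_path, panel):
    body = (
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
        "6\t100\trs1800629\tG\tA\t.\t.\t.\tGT\t0/1\t0/0\n"
        "16\t200\trs9939609\tT\tA\t.\t.\t.\tGT\t1/1\t./1\n"
        "1\t300\trs5082\tT\tC\t.\t.\t.\tGT\t0/0\t./.\n"
        "2\t400\trs999999\tG\tC\t.\t.\t.\tGT\t0/0\t0/0\n"
    )
    p = tmp_path / "g.vcf"
    p.write_text(VCF_HEADER + body)
    recs = {r.subject_id: r for r in read_vcf_genotypes(p, panel)}
    assert recs["A"].calls["rs1800629"] == ("A", "G")
    assert recs["A"].calls["rs9939609"] == ("A", "A")  # 1/1 through REF=T ALT=A
    assert recs["A"].calls["rs5082"] == ("T", "T")
    assert recs["B"].calls["rs9939609"] is None  # half-missing GT
    assert recs["B"].calls["rs5082"] is None
    assert "rs999999" not in recs["A"].calls  # non-panel site ignored


def test_vcf_rejects_incompatible_alleles(tmp_path, panel):
    body = ("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\n"
            "6\t100\trs4880\tG\tC\t.\t.\t.\tGT\t0/1\n")
    p = tmp_path / "bad.vcf"
    p.write_text(VCF_HEADER + body)
    with pytest.raises(GenotypeParseError, match="rs4880"):
        read_vcf_genotypes(p, panel)


def test_vcf_agrees_with_table_on_same_cohort(tmp_path, panel):
    records = simulate_genotypes(SimConfig(n=25, seed=11), panel)
    write_genotype_table(records, tmp_path / "g.tsv", panel)
    lines = [VCF_HEADER + "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(r.subject_id for r in records)]
    for i, snp in enumerate(panel):
        ref, alt = snp.other_allele, snp.risk_allele
        gts = []
        for r in records:
            call = r.calls[snp.rsid]
            gts.append("/".join(str({ref: 0, alt: 1}[a]) for a in call))
        lines.append(f"1\t{100 + i}\t{snp.rsid}\t{ref}\t{alt}\t.\t.\t.\tGT\t" + "\t".join(gts))
    (tmp_path / "g.vcf").write_text("\n".join(lines) + "\n")
    from_table = read_genotype_table(tmp_path / "g.tsv", panel)
    from_vcf = read_vcf_genotypes(tmp_path / "g.vcf", panel)
    assert {r.subject_id: r.calls for r in from_vcf} == {
        r.subject_id: r.calls for r in from_table}


def make_phen(ids, **cols):
    return pd.DataFrame({"subject_id": ids, **cols})


def test_join_complete_case_and_keep_all(panel):
    recs = simulate_genotypes(SimConfig(n=3, seed=0), panel)
    ids = [r.subject_id for r in recs]
    phen = make_phen(ids[:2], age=[30, 40])
    cohort = join_cohort(recs, phen, policy="complete_case", panel=panel)
    assert cohort.n == 2
    assert cohort.provenance["dropped"]["no_phenotype"] == 1

    recs[0].calls["rs5082"] = None
    cohort2 = join_cohort(recs, phen, policy="complete_case", panel=panel)
    assert cohort2.n == 1
    assert cohort2.provenance["dropped"]["missing_genotype"] == 1

    all_c = join_cohort(recs, make_phen([*ids, "EXTRA"], age=[1, 2, 3, 4]),
                        policy="keep_all", panel=panel)
    assert all_c.n == 4


def test_join_required_phenotypes_and_duplicates(panel):
    recs = simulate_genotypes(SimConfig(n=2, seed=1), panel)
    ids = [r.subject_id for r in recs]
    phen = make_phen(ids, age=[30, np.nan])
    c = join_cohort(recs, phen, panel=panel, required_phenotypes=("age",))
    assert c.n == 1 and c.provenance["dropped"]["missing_phenotype"] == 1
    with pytest.raises(ValueError, match="duplicate"):
        join_cohort(recs + [GenotypeRecord(ids[0], {})], phen, panel=panel)


def test_read_phenotypes_validation(tmp_path):
    p = tmp_path / "p.csv"
    p.write_text("subject_id,age,sex,height,ht_dx\nA,30,female,1.7,1\nB,40,male,1.8,NA\n")
    df = read_phenotypes(p)
    assert df["ht_dx"].dtype.name == "boolean"
    assert df["ht_dx"][0] == True and pd.isna(df["ht_dx"][1])  # noqa: E712

    bad = tmp_path / "bad.csv"
    bad.write_text("subject_id,height\nA,-1.7\n")
    with pytest.raises(ValueError, match="height"):
        read_phenotypes(bad)
    badsex = tmp_path / "badsex.csv"
    badsex.write_text("subject_id,sex\nA,unknown\n")
    with pytest.raises(ValueError, match="sex"):
        read_phenotypes(badsex)
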