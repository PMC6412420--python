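{
  "name": "LGI-Ob",
  "version": "1.0",
  "description": "Default 5-SNP panel for the genetic score of predisposition to low-grade inflammation associated with obesity. Per-genotype integer risk weights; rs1800629 uses a dominant coding (heterozygote carries the full risk weight).",
  "snps": [
    {
      "rsid": "rs1800629",
      "gene": "TNFA",
      "alleles": ["G", "A"],
      "weights": {"GG": 0, "GA": 2, "AA": 2}
    },
    {
      "rsid": "rs5082",
      "gene": "APOA2",
      "alleles": ["C", "T"],
      "weights": {"CC": 0, "TC": 1, "TT": 2}
    },
    {
      "rsid": "rs4880",
      "gene": "SOD2",
      "alleles": ["C", "T"],
      "weights": {"CC": 0, "CT": 1, "TT": 2}
    },
    {
      "rsid": "rs1260326",
      "gene": "GCKR",
      "alleles": ["C", "T"],
      "weights": {"CC": 0, "CT": 1, "TT": 2}
    },
    {
      "rsid": "rs9939609",
      "gene": "FTO",
      "alleles": ["T", "A"],
      "weights": {"TT": 0, "TA": 1, "AA": 2}
    }
  ]
}
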