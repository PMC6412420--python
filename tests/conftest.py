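import itertools

import pytest

from lgiob.cohort import GenotypeRecord
from lgiob.panel import default_panel


@pytest.fixture(scope="session")
def panel():
    return default_panel()


# Independent weight-table oracle for the default panel, written out by hand
# as (rsID, genotype string) -> weight so the score engine can be checked by
# pure dictionary lookup.
WEIGHT_ORACLE = {
    ("rs1800629", "GG"): 0, ("rs1800629", "GA"): 2, ("rs1800629", "AA"): 2,
    ("rs5082", "CC"): 0, ("rs5082", "TC"): 1, ("rs5082", "TT"): 2,
    ("rs4880", "CC"): 0, ("rs4880", "CT"): 1, ("rs4880", "TT"): 2,
    ("rs1260326", "CC"): 0, ("rs1260326", "CT"): 1, ("rs1260326", "TT"): 2,
    ("rs9939609", "TT"): 0, ("rs9939609", "TA"): 1, ("rs9939609", "AA"): 2,
}

GENOTYPE_SPELLINGS = {
    "rs1800629": ("GG", "GA", "AA"),
    "rs5082": ("CC", "TC", "TT"),
    "rs4880": ("CC", "CT", "TT"),
    "rs1260326": ("CC", "CT", "TT"),
    "rs9939609": ("TT", "TA", "AA"),
}


def all_genotype_combinations():
    """All 3^5 genotype combinations of the default panel, as spelled tuples."""
    rsids = list(GENOTYPE_SPELLINGS)
    for combo in itertools.product(*(GENOTYPE_SPELLINGS[r] for r in rsids)):
        yield dict(zip(rsids, combo))


def record_from_spelled(subject_id: str, spelled: dict) -> GenotypeRecord:
    return GenotypeRecord(subject_id, {r: tuple(sorted(g)) for r, g in spelled.items()})
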