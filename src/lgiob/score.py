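"""Genetic-score engine: additive per-genotype weights and dichotomization.

The score of a subject is the sum over panel SNPs of the integer risk weight
of the subject's genotype (0-10 for the default 5-SNP panel).  Subjects are
stratified into a low (< threshold) and a high (>= threshold) group; the
default cut of 5 corresponds to one above the population median of 4
observed for this score, and an alternative policy derives the cut from the
median of the cohort at hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .panel import MissingGenotypeError, SnpPanel, genotype_weight

__all__ = [
    "ScoreResult",
    "compute_score",
    "stratify",
    "score_summary",
    "score_table",
    "median_threshold",
    "DEFAULT_THRESHOLD",
]

#: Fixed dichotomization cut: scores >= 5 are "high".
DEFAULT_THRESHOLD = 5

Stratum = Literal["low", "high"]


@dataclass(frozen=True)
class ScoreResult:
    """Per-subject score with its per-SNP breakdown.

    ``score`` and ``stratum`` are ``None`` for unscorable subjects (any
    missing genotype); the breakdown then carries ``None`` at the missing
    SNPs.  The breakdown is retained so that panel-reduction sensitivity
    analyses can recompute scores without re-reading genotypes.
    """

    subject_id: str
    score: int | None
    stratum: Stratum | None
    breakdown: dict[str, int | None]

    @property
    def scorable(self) -> bool:
        return self.score is not None


def stratify(score: int, threshold: int = DEFAULT_THRESHOLD) -> Stratum:
    """Dichotomize a score: ``low`` iff score < threshold."""
    return "low" if score < threshold else "high"


def compute_score(record, panel: SnpPanel, threshold: int = DEFAULT_THRESHOLD) -> ScoreResult:
    """Score one genotype record against a panel.

    ``record`` is any object with ``subject_id`` and ``calls`` (mapping
    rsID -> unordered allele pair or None).  A subject missing any panel
    genotype is flagged unscorable rather than scored low.
    """
    breakdown: dict[str, int | None] = {}
    complete = True
    for snp in panel:
        call = record.calls.get(snp.rsid)
        if call is None:
            breakdown[snp.rsid] = None
            complete = False
        else:
            breakdown[snp.rsid] = genotype_weight(snp, call)
    if not complete:
        return ScoreResult(record.subject_id, None, None, breakdown)
    total = sum(breakdown.values())  # type: ignore[arg-type]
    return ScoreResult(record.subject_id, total, stratify(total, threshold), breakdown)


def score_table(
    records: Iterable,
    panel: SnpPanel,
    threshold: int = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Score a collection of genotype records into a tidy frame.

    Columns: subject_id, one weight column per rsID (nullable integers),
    score, stratum.  Unscorable subjects keep NA score/stratum.
    """
    rows = []
    for rec in records:
        res = compute_score(rec, panel, threshold)
        row: dict = {"subject_id": res.subject_id}
        row.update(res.breakdown)
        row["score"] = res.score
        row["stratum"] = res.stratum
        rows.append(row)
    df = pd.DataFrame(rows, columns=["subject_id", *panel.rsids, "score", "stratum"])
    for col in (*panel.rsids, "score"):
        df[col] = df[col].astype("Int64")
    return df


def median_threshold(scores: Sequence[int]) -> int:
    """Cohort-derived cut: the smallest integer strictly above the median.

    With a median of 4 this reproduces the fixed default of 5.
    """
    med = float(np.median(np.asarray(scores)))
    return int(np.floor(med)) + 1


def score_summary(scores: Sequence[int]) -> dict:
    """Distribution summary of a score vector.

    Returns median, IQR (Q3 - Q1), mean, SD (ddof=1; 0 for a single value)
    and a histogram over the full integer support.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise ValueError("score_summary requires at least one score")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    support = np.arange(int(arr.min()), int(arr.max()) + 1)
    counts = {int(s): int((arr == s).sum()) for s in support}
    return {
        "n": int(arr.size),
        "median": float(med),
        "iqr": float(q3 - q1),
        "mean": float(arr.mean()),
        "sd": sd,
        "histogram": counts,
    }
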