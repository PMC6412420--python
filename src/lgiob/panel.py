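"""SNP panel definitions: the weight scheme behind the genetic score.

A panel is an ordered list of biallelic SNPs, each carrying an integer risk
weight for every one of its three genotypes.  Weights are data, not code:
the default panel ships as a JSON config bundled with the package, and any
other additive genotype-weight score can reuse the same engine by supplying
its own config.

Genotypes are unordered allele pairs; internally they are normalized to an
alphabetically sorted two-tuple, so ``("G", "A")`` and ``("A", "G")`` name
the same genotype.  Display spelling follows the config file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Iterator, Mapping

__all__ = [
    "Genotype",
    "SnpDef",
    "SnpPanel",
    "PanelError",
    "normalize_genotype",
    "genotype_weight",
    "default_panel",
    "load_panel",
]

Genotype = tuple[str, str]


class PanelError(ValueError):
    """Invalid panel definition or a call inconsistent with the panel."""


def normalize_genotype(call: Iterable[str] | str) -> Genotype:
    """Return the unordered genotype as an alphabetically sorted tuple.

    Accepts a two-letter string (``"GA"``) or any iterable of two
    single-letter allele symbols.
    """
    alleles = tuple(call)
    if len(alleles) != 2 or not all(isinstance(a, str) and len(a) == 1 for a in alleles):
        raise PanelError(f"genotype must be exactly two single-letter alleles, got {call!r}")
    a, b = sorted(alleles)
    return (a, b)


@dataclass(frozen=True)
class SnpDef:
    """One biallelic SNP with its genotype-to-weight mapping.

    ``weights`` is keyed by normalized genotype; ``display`` keeps the
    spelling used in the source config for round-tripping.
    """

    rsid: str
    gene: str
    alleles: frozenset[str]
    weights: Mapping[Genotype, int]
    display: Mapping[Genotype, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise PanelError(f"{self.rsid}: panel SNPs are biallelic, got alleles {set(self.alleles)}")
        if len(self.weights) != 3:
            raise PanelError(f"{self.rsid}: expected exactly 3 genotypes, got {len(self.weights)}")
        for g, w in self.weights.items():
            if not set(g) <= self.alleles:
                raise PanelError(f"{self.rsid}: genotype {g} uses alleles outside {set(self.alleles)}")
            if w not in (0, 1, 2):
                raise PanelError(f"{self.rsid}: weight {w} outside {{0,1,2}}")

    @property
    def genotypes(self) -> tuple[Genotype, ...]:
        return tuple(self.weights)

    @property
    def max_weight(self) -> int:
        return max(self.weights.values())

    @property
    def risk_allele(self) -> str:
        """The allele whose homozygote carries the maximum weight."""
        hom = max(
            (g for g in self.weights if g[0] == g[1]),
            key=lambda g: self.weights[g],
        )
        return hom[0]

    @property
    def other_allele(self) -> str:
        (a,) = self.alleles - {self.risk_allele}
        return a

    def genotype_for_risk_count(self, k: int) -> Genotype:
        """Genotype carrying ``k`` copies of the risk allele (k in 0..2)."""
        r, o = self.risk_allele, self.other_allele
        return normalize_genotype([r] * k + [o] * (2 - k))

    def weight(self, call: Iterable[str] | str) -> int:
        g = normalize_genotype(call)
        if not set(g) <= self.alleles:
            raise PanelError(
                f"{self.rsid}: alleles {set(g)} not in panel allele set {set(self.alleles)}"
            )
        return self.weights[g]


def genotype_weight(snp: SnpDef, call: Iterable[str] | str) -> int:
    """Risk weight of an unordered genotype call at one SNP.

    Raises :class:`MissingGenotypeError` on a missing call (``None``) so the
    caller can distinguish "no data" from a genuine weight of 0, and
    :class:`PanelError` on alleles foreign to the SNP.
    """
    if call is None:
        raise MissingGenotypeError(f"{snp.rsid}: missing genotype has no weight")
    return snp.weight(call)


class MissingGenotypeError(ValueError):
    """A weight was requested for a missing genotype call."""


@dataclass(frozen=True)
class SnpPanel:
    """Ordered collection of :class:`SnpDef` making up one score."""

    snps: tuple[SnpDef, ...]
    name: str = "panel"
    version: str = "0"

    def __post_init__(self) -> None:
        seen = [s.rsid for s in self.snps]
        if len(set(seen)) != len(seen):
            raise PanelError(f"duplicate rsIDs in panel: {seen}")

    def __iter__(self) -> Iterator[SnpDef]:
        return iter(self.snps)

    def __len__(self) -> int:
        return len(self.snps)

    def __contains__(self, rsid: str) -> bool:
        return any(s.rsid == rsid for s in self.snps)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(s.rsid for s in self.snps)

    @property
    def max_score(self) -> int:
        """Maximum attainable total score (sum of per-SNP maxima)."""
        return sum(s.max_weight for s in self.snps)

    def get(self, rsid: str) -> SnpDef:
        for s in self.snps:
            if s.rsid == rsid:
                return s
        raise PanelError(f"rsID {rsid!r} not in panel {self.name}")

    def drop(self, rsid: str) -> "SnpPanel":
        """New panel without ``rsid`` (e.g. the FTO-removal sensitivity run)."""
        self.get(rsid)  # raise on unknown rsID
        return SnpPanel(
            snps=tuple(s for s in self.snps if s.rsid != rsid),
            name=f"{self.name}-minus-{rsid}",
            version=self.version,
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "version": self.version,
            "snps": [
                {
                    "rsid": s.rsid,
                    "gene": s.gene,
                    "alleles": sorted(s.alleles),
                    "weights": {s.display.get(g, "".join(g)): w for g, w in s.weights.items()},
                }
                for s in self.snps
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SnpPanel":
        snps = []
        for entry in d["snps"]:
            weights: dict[Genotype, int] = {}
            display: dict[Genotype, str] = {}
            for spelled, w in entry["weights"].items():
                g = normalize_genotype(spelled)
                if g in weights:
                    raise PanelError(f"{entry['rsid']}: duplicate genotype {spelled}")
                weights[g] = int(w)
                display[g] = spelled
            snps.append(
                SnpDef(
                    rsid=entry["rsid"],
                    gene=entry.get("gene", ""),
                    alleles=frozenset(entry["alleles"]),
                    weights=weights,
                    display=display,
                )
            )
        return cls(snps=tuple(snps), name=d.get("name", "panel"), version=str(d.get("version", "0")))


def load_panel(path) -> SnpPanel:
    """Load a panel from a JSON config file."""
    with open(path) as fh:
        return SnpPanel.from_dict(json.load(fh))


def default_panel() -> SnpPanel:
    """The bundled default 5-SNP panel (TNFA, APOA2, SOD2, GCKR, FTO)."""
    text = resources.files("lgiob.data").joinpath("default_panel.json").read_text()
    return SnpPanel.from_dict(json.loads(text))
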