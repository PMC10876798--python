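"""Core data model: loci, genotypes, grouped cohorts and per-locus counts.

The package works on a fixed four-SNP pharmacogene panel (NUDT15
rs116855232; TPMT rs1800462, rs1800460, rs1142345). Genotypes are stored
unphased — TaqMan allele discrimination, the assay class these panels are
typed with, yields no phase — and any phase present in input files is
discarded. The alt allele is the panel-defined variant allele and is never
re-polarized by frequency, so reported MAFs are variant-allele frequencies
even if one exceeds 0.5 in some group.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping


class Genotype(str, enum.Enum):
    """Unphased diploid genotype at a biallelic site."""

    HOM_REF = "hom_ref"
    HET = "het"
    HOM_ALT = "hom_alt"
    MISSING = "missing"

    @property
    def dosage(self) -> int | None:
        """Count of alt alleles, or None when missing."""
        return {"hom_ref": 0, "het": 1, "hom_alt": 2, "missing": None}[self.value]

    @classmethod
    def from_dosage(cls, d: int | None) -> "Genotype":
        if d is None:
            return cls.MISSING
        return (cls.HOM_REF, cls.HET, cls.HOM_ALT)[d]

    @classmethod
    def from_gt_token(cls, token: str) -> "Genotype":
        """Parse a VCF-style GT token ("0/0", "0|1", "./."); phase is ignored."""
        alleles = token.replace("|", "/").split("/")
        if len(alleles) != 2:
            raise ValueError(f"not a diploid genotype token: {token!r}")
        if "." in alleles:
            return cls.MISSING
        try:
            dose = sum(int(a) for a in alleles)
        except ValueError:
            raise ValueError(f"unrecognized genotype token: {token!r}") from None
        if any(int(a) not in (0, 1) for a in alleles):
            raise ValueError(f"non-biallelic genotype token: {token!r}")
        return cls.from_dosage(dose)

    def to_gt_token(self) -> str:
        return {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", "missing": "./."}[
            self.value
        ]


@dataclass(frozen=True)
class Locus:
    """A biallelic panel site. ``alt_allele`` is the variant (minor) allele."""

    id: str
    gene: str
    ref_allele: str
    alt_allele: str
    cdna_label: str = ""
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.id}: ref and alt alleles must differ")


# The thiopurine panel. Coordinates are GRCh38 and used only to match VCF
# records when IDs are absent.
PANEL: tuple[Locus, ...] = (
    Locus("rs116855232", "NUDT15", "C", "T", "c.415C>T", "13", 48037782),
    Locus("rs1800462", "TPMT", "G", "C", "c.238G>C", "6", 18149127),
    Locus("rs1800460", "TPMT", "G", "A", "c.460G>A", "6", 18143955),
    Locus("rs1142345", "TPMT", "A", "G", "c.719A>G", "6", 18139228),
)

TPMT_LOCI: tuple[str, ...] = ("rs1800462", "rs1800460", "rs1142345")
NUDT15_LOCI: tuple[str, ...] = ("rs116855232",)

GROUPS: tuple[str, ...] = ("Yanomami", "Munduruku", "Paiter-Surui")


def panel_by_id(panel: Iterable[Locus] = PANEL) -> dict[str, Locus]:
    return {loc.id: loc for loc in panel}


@dataclass
class Individual:
    individual_id: str
    group: str
    genotypes: dict[str, Genotype]

    def genotype(self, locus_id: str) -> Genotype:
        return self.genotypes.get(locus_id, Genotype.MISSING)


@dataclass
class GroupedCohort:
    """Per-individual unphased genotypes at panel loci, with group labels."""

    individuals: list[Individual]
    loci: tuple[Locus, ...] = PANEL

    def __post_init__(self) -> None:
        ids = [ind.individual_id for ind in self.individuals]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual_id(s): {dup}")
        known = {loc.id for loc in self.loci}
        for ind in self.individuals:
            unknown = set(ind.genotypes) - known
            if unknown:
                raise ValueError(
                    f"{ind.individual_id}: genotypes at undeclared loci {sorted(unknown)}"
                )

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.group, None)
        return list(seen)

    def subset(self, group: str) -> "GroupedCohort":
        return GroupedCohort(
            [ind for ind in self.individuals if ind.group == group], self.loci
        )

    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for ind in self.individuals:
            sizes[ind.group] = sizes.get(ind.group, 0) + 1
        return sizes


@dataclass(frozen=True)
class GenotypeCounts:
    """Integer genotype-class counts for one (group, locus) cell.

    The unit of all frequency statistics: missing individuals are carried
    explicitly so that typed and nominal denominators stay distinguishable.
    """

    group: str
    locus_id: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        for name in ("n_hom_ref", "n_het", "n_hom_alt", "n_missing"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_typed(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def n_total(self) -> int:
        return self.n_typed + self.n_missing

    @property
    def counts(self) -> tuple[int, int, int]:
        return (self.n_hom_ref, self.n_het, self.n_hom_alt)

    @property
    def alt_allele_count(self) -> int:
        return self.n_het + 2 * self.n_hom_alt


@dataclass(frozen=True)
class FrequencyRow:
    """A published genotype-frequency row: proportions rounded to 3 decimals."""

    group: str
    locus_id: str
    f_hom_ref: float
    f_het: float
    f_hom_alt: float
    maf: float

    def __post_init__(self) -> None:
        for name in ("f_hom_ref", "f_het", "f_hom_alt", "maf"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        s = self.f_hom_ref + self.f_het + self.f_hom_alt
        if not 0.997 <= s <= 1.003:
            raise ValueError(f"genotype proportions sum to {s}, outside rounding slack")

    @property
    def proportions(self) -> tuple[float, float, float]:
        return (self.f_hom_ref, self.f_het, self.f_hom_alt)
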