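"""Star-allele diplotype assignment from unphased panel genotypes.

A star allele is a named haplotype of a pharmacogene defined by the set of
panel variants it carries (*1 is the reference haplotype with an empty
variant set). Calling works by exhaustive consistency: every unordered pair
of defined haplotypes whose summed per-locus alt-allele counts exactly
reproduce the observed unphased genotype is a candidate diplotype.

With the TPMT panel (*1, *2, *3A, *3B, *3C) the only ambiguous pattern is
the rs1800460/rs1142345 double heterozygote, compatible with *1/*3A and
*3B/*3C. The default policy resolves it to *1/*3A (fewest variant
haplotypes), which matches the strong positive linkage between the two
sites in every population where both are common; an EM-frequency policy is
available as an alternative. The choice is not phenotype-neutral — *1/*3A
is IM while *3B/*3C is PM — but the miscall rate of the default policy is
the population frequency of true *3B/*3C pairings among double
heterozygotes, 2·f(*3B)·f(*3C) / (2·f(*1)·f(*3A) + 2·f(*3B)·f(*3C)),
negligible wherever *3B and *3C are rare.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .model import PANEL, Genotype, GroupedCohort, Locus

NO_CALL = "no_call"


@dataclass(frozen=True)
class HaplotypeDefinition:
    """One star allele: the panel variants on the haplotype and its CPIC
    functional status."""

    gene: str
    star_name: str
    variant_set: frozenset[str]
    function: str  # "normal" or "no_function"

    def dose(self, locus_id: str) -> int:
        return 1 if locus_id in self.variant_set else 0


def load_allele_definitions(path: str | Path | None = None) -> list[HaplotypeDefinition]:
    """Load star-allele definitions (and functionality) from YAML config.

    Defaults to the packaged table mirroring the CPIC TPMT/NUDT15
    definition and functionality tables for this panel.
    """
    if path is None:
        from .genotype_io import data_path

        path = data_path("allele_definitions.yaml")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    defs: list[HaplotypeDefinition] = []
    for gene, alleles in raw.items():
        seen_sets: set[frozenset[str]] = set()
        for entry in alleles:
            vs = frozenset(entry.get("variants") or [])
            if vs in seen_sets:
                raise ValueError(f"{gene}: duplicate variant set for {entry['star']}")
            seen_sets.add(vs)
            defs.append(HaplotypeDefinition(gene, entry["star"], vs, entry["function"]))
    for gene in raw:
        stars = [d for d in defs if d.gene == gene]
        if not any(not d.variant_set for d in stars):
            raise ValueError(f"{gene}: no reference (*1) haplotype defined")
    return defs


def gene_definitions(
    definitions: Iterable[HaplotypeDefinition], gene: str
) -> list[HaplotypeDefinition]:
    out = [d for d in definitions if d.gene == gene]
    if not out:
        raise ValueError(f"no haplotype definitions for gene {gene}")
    return out


def gene_loci(gene: str, panel: Sequence[Locus] = PANEL) -> list[str]:
    return [loc.id for loc in panel if loc.gene == gene]


@dataclass
class Diplotype:
    individual_id: str
    gene: str
    hap1: str
    hap2: str
    ambiguous: bool = False
    candidates: list[tuple[str, str]] = field(default_factory=list)
    rationale: str = ""

    @property
    def is_call(self) -> bool:
        return self.hap1 != NO_CALL

    @property
    def pair(self) -> tuple[str, str]:
        return (self.hap1, self.hap2)

    def __str__(self) -> str:
        return f"{self.gene} {self.hap1}/{self.hap2}"


def diplotype_to_genotypes(
    hap1: HaplotypeDefinition,
    hap2: HaplotypeDefinition,
    loci: Sequence[str],
) -> dict[str, Genotype]:
    """Synthesize the unphased genotypes implied by a haplotype pair."""
    return {
        lid: Genotype.from_dosage(hap1.dose(lid) + hap2.dose(lid)) for lid in loci
    }


def enumerate_consistent_pairs(
    genotypes: Mapping[str, Genotype],
    definitions: Sequence[HaplotypeDefinition],
    loci: Sequence[str] | None = None,
) -> list[tuple[str, str]]:
    """Every unordered haplotype pair whose implied per-locus alt-allele
    counts match the observed genotype exactly.

    Requires a complete (no-missing) genotype over the gene's loci. Pair
    order within a tuple, and pairs in the returned list, follow the order
    of the definition table (*1 first).
    """
    if loci is None:
        loci = list(genotypes)
    for lid in loci:
        g = genotypes.get(lid, Genotype.MISSING)
        if g is Genotype.MISSING:
            raise ValueError(f"missing genotype at {lid}; cannot enumerate pairs")
    observed = {lid: genotypes[lid].dosage for lid in loci}
    pairs: list[tuple[str, str]] = []
    for h1, h2 in itertools.combinations_with_replacement(definitions, 2):
        if all(h1.dose(lid) + h2.dose(lid) == observed[lid] for lid in loci):
            pairs.append((h1.star_name, h2.star_name))
    return pairs


def _n_variant_haps(pair: tuple[str, str], ref_star: str) -> int:
    return sum(1 for s in pair if s != ref_star)


def call_diplotype(
    individual_id: str,
    genotypes: Mapping[str, Genotype],
    definitions: Sequence[HaplotypeDefinition],
    gene: str,
    policy: str = "prefer_fewest_variant_haplotypes",
    hap_freqs: Mapping[str, float] | None = None,
    panel: Sequence[Locus] = PANEL,
) -> Diplotype:
    """Call one gene's diplotype for one individual.

    Policies for multi-candidate genotypes:

    - ``prefer_fewest_variant_haplotypes`` (default): choose the pair with
      the fewest non-reference haplotypes.
    - ``em_frequency``: choose the pair with the highest Hardy-Weinberg
      probability under supplied haplotype frequencies (``hap_freqs``).

    Any missing genotype at the gene's loci yields a no-call (no
    imputation is attempted).
    """
    defs = gene_definitions(definitions, gene)
    loci = gene_loci(gene, panel)
    ref_star = next(d.star_name for d in defs if not d.variant_set)

    if any(genotypes.get(lid, Genotype.MISSING) is Genotype.MISSING for lid in loci):
        return Diplotype(
            individual_id, gene, NO_CALL, NO_CALL,
            rationale="missing genotype at one or more panel loci",
        )

    pairs = enumerate_consistent_pairs(genotypes, defs, loci)
    if not pairs:
        return Diplotype(
            individual_id, gene, NO_CALL, NO_CALL,
            rationale="genotype not representable by any defined haplotype pair",
        )
    if len(pairs) == 1:
        return Diplotype(individual_id, gene, *pairs[0], candidates=pairs)

    if policy == "prefer_fewest_variant_haplotypes":
        chosen = min(pairs, key=lambda p: (_n_variant_haps(p, ref_star), p))
        why = "fewest variant haplotypes among candidates"
    elif policy == "em_frequency":
        if hap_freqs is None:
            raise ValueError("em_frequency policy requires hap_freqs")

        def hw_prob(p: tuple[str, str]) -> float:
            f1 = hap_freqs.get(p[0], 0.0)
            f2 = hap_freqs.get(p[1], 0.0)
            return f1 * f2 * (2.0 if p[0] != p[1] else 1.0)

        chosen = max(pairs, key=hw_prob)
        why = "highest diplotype probability under haplotype frequencies"
    else:
        raise ValueError(f"unknown ambiguity policy: {policy}")
    return Diplotype(
        individual_id, gene, *chosen, ambiguous=True, candidates=pairs, rationale=why
    )


def call_cohort(
    cohort: GroupedCohort,
    definitions: Sequence[HaplotypeDefinition],
    genes: Sequence[str] = ("TPMT", "NUDT15"),
    policy: str = "prefer_fewest_variant_haplotypes",
    hap_freqs: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, list[Diplotype]]:
    """Call every individual at every requested gene."""
    out: dict[str, list[Diplotype]] = {}
    for gene in genes:
        freqs = hap_freqs.get(gene) if hap_freqs else None
        out[gene] = [
            call_diplotype(
                ind.individual_id, ind.genotypes, definitions, gene,
                policy=policy, hap_freqs=freqs, panel=cohort.loci,
            )
            for ind in cohort.individuals
        ]
    return out


def star_frequencies(
    diplotypes: Sequence[Diplotype],
    group_of: Mapping[str, str],
    decimals: int = 3,
) -> pd.DataFrame:
    """Per-group star-allele counts and frequencies over 2 x n_called
    chromosomes. No-calls are excluded from the denominator."""
    from .count_reconstruct import round_half_up

    records = []
    for d in diplotypes:
        if not d.is_call:
            continue
        g = group_of[d.individual_id]
        records.append((g, d.hap1))
        records.append((g, d.hap2))
    df = pd.DataFrame(records, columns=["group", "star"])
    if df.empty:
        return pd.DataFrame(columns=["group", "star", "count", "n_chromosomes", "freq"])
    counts = df.groupby(["group", "star"]).size().rename("count").reset_index()
    totals = df.groupby("group").size().rename("n_chromosomes")
    counts = counts.join(totals, on="group")
    counts["freq"] = [
        round_half_up(c / t, decimals)
        for c, t in zip(counts["count"], counts["n_chromosomes"])
    ]
    return counts
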