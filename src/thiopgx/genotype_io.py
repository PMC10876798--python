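"""Cohort I/O: TSV and VCF readers/writers, tabulation, packaged fixtures.

TSV dialect: tab-separated, UTF-8, lines starting with "#" ignored. Header
columns are ``individual_id``, ``group``, then one column per panel locus
holding VCF-style GT tokens ("0/0", "0/1", "1/1", "./."). VCF input/output
is v4.x via pysam; records are matched to the panel by ID first, then by
chrom/pos/ref/alt, and phase separators are accepted but discarded.
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pysam

from .model import (
    PANEL,
    FrequencyRow,
    Genotype,
    GenotypeCounts,
    GroupedCohort,
    Individual,
    Locus,
    panel_by_id,
)

_VALID_TOKENS = {"0/0", "0/1", "1/0", "1/1", "./."}


def read_cohort_tsv(
    path: str | Path, locus_panel: Iterable[Locus] = PANEL
) -> GroupedCohort:
    """Read a grouped cohort from a TSV genotype table."""
    panel = tuple(locus_panel)
    with open(path, encoding="utf-8") as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if not line.startswith("#")]
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    if header[:2] != ["individual_id", "group"]:
        raise ValueError(f"{path}: header must start with individual_id, group")
    for loc in panel:
        if loc.id not in header:
            raise ValueError(f"{path}: missing column for locus {loc.id}")
    col = {name: i for i, name in enumerate(header)}

    individuals = []
    for row in rows[1:]:
        if not any(row):
            continue
        genos: dict[str, Genotype] = {}
        for loc in panel:
            token = row[col[loc.id]]
            if token not in _VALID_TOKENS:
                raise ValueError(
                    f"{path}: unknown genotype token {token!r} at {loc.id} "
                    f"for {row[0]}"
                )
            genos[loc.id] = Genotype.from_gt_token(token)
        individuals.append(Individual(row[col["individual_id"]], row[col["group"]], genos))
    return GroupedCohort(individuals, panel)


def write_cohort_tsv(cohort: GroupedCohort, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["individual_id", "group"] + [loc.id for loc in cohort.loci])
        for ind in cohort.individuals:
            writer.writerow(
                [ind.individual_id, ind.group]
                + [ind.genotype(loc.id).to_gt_token() for loc in cohort.loci]
            )


def read_cohort_vcf(
    path: str | Path,
    locus_panel: Iterable[Locus] = PANEL,
    group_map: Mapping[str, str] | None = None,
) -> GroupedCohort:
    """Read a grouped cohort from a VCF. ``group_map`` assigns each sample to
    a group; every sample in the file must be mapped."""
    panel = tuple(locus_panel)
    if group_map is None:
        raise ValueError("group_map is required for VCF input")
    by_id = panel_by_id(panel)
    by_site = {(loc.chrom, loc.pos, loc.ref_allele, loc.alt_allele): loc for loc in panel}

    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        missing = [s for s in samples if s not in group_map]
        if missing:
            raise ValueError(f"samples absent from group_map: {missing}")
        genos: dict[str, dict[str, Genotype]] = {s: {} for s in samples}
        seen: set[str] = set()
        for rec in vcf:
            locus = by_id.get(rec.id) if rec.id else None
            if locus is None:
                alts = rec.alts or ()
                alt = alts[0] if len(alts) == 1 else None
                locus = by_site.get((rec.chrom, rec.pos, rec.ref, alt))
            if locus is None:
                continue
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(f"{locus.id}: multiallelic record not supported")
            seen.add(locus.id)
            for s in samples:
                alleles = rec.samples[s]["GT"]
                if alleles is None or any(a is None for a in alleles):
                    genos[s][locus.id] = Genotype.MISSING
                else:
                    genos[s][locus.id] = Genotype.from_dosage(sum(alleles))
    absent = [loc.id for loc in panel if loc.id not in seen]
    if absent:
        raise ValueError(f"panel site(s) absent from VCF: {absent}")
    individuals = [Individual(s, group_map[s], genos[s]) for s in samples]
    return GroupedCohort(individuals, panel)


def write_cohort_vcf(cohort: GroupedCohort, path: str | Path) -> None:
    """Write the cohort as an uncompressed VCF v4.2 (unphased GTs)."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for chrom in dict.fromkeys(loc.chrom for loc in cohort.loci):
        header.contigs.add(chrom)
    for ind in cohort.individuals:
        header.add_sample(ind.individual_id)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for loc in sorted(cohort.loci, key=lambda l: (l.chrom, l.pos)):
            rec = out.new_record(
                contig=loc.chrom,
                start=loc.pos - 1,
                stop=loc.pos,
                alleles=(loc.ref_allele, loc.alt_allele),
                id=loc.id,
            )
            for ind in cohort.individuals:
                g = ind.genotype(loc.id)
                gt = {
                    Genotype.HOM_REF: (0, 0),
                    Genotype.HET: (0, 1),
                    Genotype.HOM_ALT: (1, 1),
                    Genotype.MISSING: (None, None),
                }[g]
                rec.samples[ind.individual_id]["GT"] = gt
                rec.samples[ind.individual_id].phased = False
            out.write(rec)


def tabulate_counts(cohort: GroupedCohort) -> list[GenotypeCounts]:
    """Count genotype classes per (group, locus); counts plus missing sum to
    the group size."""
    out: list[GenotypeCounts] = []
    for group in cohort.groups:
        members = [ind for ind in cohort.individuals if ind.group == group]
        for loc in cohort.loci:
            tally = {g: 0 for g in Genotype}
            for ind in members:
                tally[ind.genotype(loc.id)] += 1
            out.append(
                GenotypeCounts(
                    group,
                    loc.id,
                    tally[Genotype.HOM_REF],
                    tally[Genotype.HET],
                    tally[Genotype.HOM_ALT],
                    tally[Genotype.MISSING],
                )
            )
    return out


# ---------------------------------------------------------------------------
# Packaged fixtures


def data_path(name: str) -> Path:
    return Path(str(resources.files("thiopgx").joinpath("data", name)))


def load_published_frequencies(name: str = "genotype_frequencies.tsv") -> list[FrequencyRow]:
    """Published per-group genotype proportions and MAFs for the panel
    (three Amazonian cohorts, nominal n = 90 each)."""
    rows: list[FrequencyRow] = []
    with open(data_path(name), encoding="utf-8") as fh:
        reader = csv.DictReader(
            (l for l in fh if not l.startswith("#")), delimiter="\t"
        )
        for rec in reader:
            rows.append(
                FrequencyRow(
                    rec["group"],
                    rec["locus_id"],
                    float(rec["f_hom_ref"]),
                    float(rec["f_het"]),
                    float(rec["f_hom_alt"]),
                    float(rec["maf"]),
                )
            )
    return rows


def load_joint_fixture() -> GroupedCohort:
    """The pinned 270-individual reconstruction of the three-cohort study
    (see :mod:`thiopgx.fixtures` for how it is built and what it pins)."""
    return read_cohort_tsv(data_path("joint_cohort_fixture.tsv"))
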