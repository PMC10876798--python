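"""End-to-end reanalysis of the published tables and the pinned cohort.

This module chains the primitives into the study's actual analyses:

1. reconstruct integer genotype counts from the printed frequency table;
2. recompute allele frequencies, HWE and FST from those counts;
3. rebuild per-individual TPMT genotypes from the marginal counts (under
   the maximal-LD coupling the published haplotype analysis presupposes),
   call star-allele diplotypes and form the group x phenotype homogeneity
   table with Cramér's V;
4. run the CPIC engine on the pinned joint cohort for the dosing-category
   percentages.

Every function returns plain dataclasses/DataFrames so drivers, the CLI
and tests share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .count_reconstruct import ReconstructionResult, reconstruct_counts, round_half_up
from .cpic_engine import cohort_phenotype_report, functionality_map, phenotype_from_diplotype
from .genotype_io import load_joint_fixture, load_published_frequencies
from .model import PANEL, FrequencyRow, Genotype, GenotypeCounts, GroupedCohort, Individual
from .popgen_stats import (
    FstResult,
    HomogeneityResult,
    HweResult,
    allele_freq,
    fst_multigroup,
    homogeneity_test,
    hwe_test,
)
from .star_caller import call_diplotype, gene_loci, load_allele_definitions

NOMINAL_N = 90
N_WINDOW = 5


def reconstruct_published_table(
    rows: Sequence[FrequencyRow] | None = None,
    n_nominal: int = NOMINAL_N,
    window: int = N_WINDOW,
) -> dict[tuple[str, str], ReconstructionResult]:
    """Reconstruct counts for every printed (group, locus) row."""
    if rows is None:
        rows = load_published_frequencies()
    lo, hi = max(1, n_nominal - window), n_nominal + window
    return {
        (r.group, r.locus_id): reconstruct_counts(r, (lo, hi), n_nominal=n_nominal)
        for r in rows
    }


def recomputed_maf(rec: ReconstructionResult) -> float:
    """Allele frequency from reconstructed counts, rounded to 3 decimals."""
    counts = rec.to_genotype_counts()
    freq, _, _ = allele_freq(counts)
    return round_half_up(freq, 3)


def maf_table(
    recs: Mapping[tuple[str, str], ReconstructionResult]
) -> pd.DataFrame:
    rows = []
    for (group, locus), rec in recs.items():
        rows.append(
            {
                "group": group,
                "locus_id": locus,
                "n_typed": rec.n_typed,
                "n_hom_ref": rec.counts[0],
                "n_het": rec.counts[1],
                "n_hom_alt": rec.counts[2],
                "residual": rec.residual,
                "unique": rec.unique,
                "maf": recomputed_maf(rec),
            }
        )
    return pd.DataFrame(rows)


def hwe_table(
    recs: Mapping[tuple[str, str], ReconstructionResult]
) -> list[HweResult]:
    return [
        hwe_test(rec.to_genotype_counts())
        for rec in recs.values()
        if rec.n_typed > 0
    ]


def fst_by_locus(
    recs: Mapping[tuple[str, str], ReconstructionResult] | None = None,
    printed_mafs: Mapping[str, Mapping[str, float]] | None = None,
) -> dict[str, FstResult]:
    """FST per locus, either from printed MAFs (the published route) or
    from reconstructed counts."""
    out: dict[str, FstResult] = {}
    if printed_mafs is not None:
        for locus, by_group in printed_mafs.items():
            out[locus] = fst_multigroup(dict(by_group), locus_id=locus)
        return out
    assert recs is not None
    loci = sorted({locus for (_, locus) in recs})
    for locus in loci:
        freqs = {
            group: allele_freq(rec.to_genotype_counts())[0]
            for (group, lid), rec in recs.items()
            if lid == locus and rec.n_typed > 0
        }
        if len(freqs) >= 2 and any(f > 0 for f in freqs.values()):
            out[locus] = fst_multigroup(freqs, locus_id=locus)
    return out


def printed_maf_map(
    rows: Sequence[FrequencyRow] | None = None,
) -> dict[str, dict[str, float]]:
    if rows is None:
        rows = load_published_frequencies()
    out: dict[str, dict[str, float]] = {}
    for r in rows:
        out.setdefault(r.locus_id, {})[r.group] = r.maf
    return out


# ---------------------------------------------------------------------------
# Marginals -> joint TPMT genotypes -> phenotype homogeneity


def couple_counts_comonotone(
    counts_a: GenotypeCounts, counts_b: GenotypeCounts
) -> np.ndarray:
    """Joint 3x3 genotype-class counts from two marginal count triples via
    the comonotone (maximal positive dependence) coupling.

    Variant dosages at the two loci are sorted and paired rank-by-rank, the
    joint consistent with maximal positive LD. This is the coupling the
    published haplotype analysis presupposes for the tightly linked TPMT
    pair; it is exact whenever the true LD is complete.
    """
    if counts_a.n_typed != counts_b.n_typed:
        raise ValueError(
            f"marginal typed sizes differ: {counts_a.n_typed} vs {counts_b.n_typed}"
        )
    doses_a = [2] * counts_a.n_hom_alt + [1] * counts_a.n_het + [0] * counts_a.n_hom_ref
    doses_b = [2] * counts_b.n_hom_alt + [1] * counts_b.n_het + [0] * counts_b.n_hom_ref
    joint = np.zeros((3, 3), dtype=int)
    for da, db in zip(doses_a, doses_b):
        joint[da, db] += 1
    return joint


def pseudo_cohort_from_tpmt_marginals(
    recs: Mapping[tuple[str, str], ReconstructionResult],
    groups: Sequence[str],
) -> GroupedCohort:
    """Per-individual TPMT genotypes rebuilt from marginal counts.

    rs1800460 and rs1142345 are coupled comonotonically; rs1800462 (absent
    in every printed row used here) and the NUDT15 site are filled from
    their own marginals independently (they affect no TPMT call).
    """
    individuals: list[Individual] = []
    for group in groups:
        rec_460 = recs[(group, "rs1800460")]
        rec_719 = recs[(group, "rs1142345")]
        joint = couple_counts_comonotone(
            rec_460.to_genotype_counts(), rec_719.to_genotype_counts()
        )
        i = 0
        for d460 in range(3):
            for d719 in range(3):
                for _ in range(joint[d460, d719]):
                    i += 1
                    individuals.append(
                        Individual(
                            f"{group}_m{i:03d}",
                            group,
                            {
                                "rs1800462": Genotype.HOM_REF,
                                "rs1800460": Genotype.from_dosage(d460),
                                "rs1142345": Genotype.from_dosage(d719),
                            },
                        )
                    )
    return GroupedCohort(individuals, PANEL)


def tpmt_phenotype_homogeneity(
    recs: Mapping[tuple[str, str], ReconstructionResult] | None = None,
    groups: Sequence[str] = ("Yanomami", "Munduruku", "Paiter-Surui"),
) -> tuple[pd.DataFrame, HomogeneityResult]:
    """Group x {NM, IM, PM} TPMT phenotype table from reconstructed
    marginals, with the chi-square homogeneity test and Cramér's V."""
    if recs is None:
        recs = reconstruct_published_table()
    cohort = pseudo_cohort_from_tpmt_marginals(recs, groups)
    defs = load_allele_definitions()
    func = functionality_map(defs, "TPMT")
    counts = {g: {"NM": 0, "IM": 0, "PM": 0} for g in groups}
    for ind in cohort.individuals:
        dip = call_diplotype(ind.individual_id, ind.genotypes, defs, "TPMT")
        counts[ind.group][phenotype_from_diplotype(dip, func)] += 1
    table = pd.DataFrame(counts).T[["NM", "IM", "PM"]]
    # drop phenotype columns empty in every group before testing
    nonzero = table.loc[:, table.sum(axis=0) > 0]
    result = homogeneity_test(nonzero.to_numpy())
    return table, result


# ---------------------------------------------------------------------------
# Dosing-category percentages on the pinned cohort


def dosing_report(cohort: GroupedCohort | None = None) -> dict[str, pd.DataFrame]:
    """CPIC phenotype/category report for the pinned joint cohort (or any
    cohort passed in); percentages over the nominal group size at 1 dp."""
    if cohort is None:
        cohort = load_joint_fixture()
    return cohort_phenotype_report(cohort)


@dataclass
class ReanalysisBundle:
    reconstructions: pd.DataFrame
    hwe: list[HweResult]
    fst: dict[str, FstResult]
    tpmt_phenotype_table: pd.DataFrame
    tpmt_phenotype_test: HomogeneityResult
    report: dict[str, pd.DataFrame]


def run_reanalysis(cohort: GroupedCohort | None = None) -> ReanalysisBundle:
    """The full pipeline: printed tables -> counts -> statistics, plus the
    CPIC report on the per-individual cohort."""
    recs = reconstruct_published_table()
    table, test = tpmt_phenotype_homogeneity(recs)
    return ReanalysisBundle(
        reconstructions=maf_table(recs),
        hwe=hwe_table(recs),
        fst=fst_by_locus(printed_mafs=printed_maf_map()),
        tpmt_phenotype_table=table,
        tpmt_phenotype_test=test,
        report=dosing_report(cohort),
    )
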