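"""Diplotype -> metabolic phenotype -> thiopurine dosing category.

CPIC assigns a gene-level metabolic phenotype from the number of
no-function haplotypes in the diplotype: 0 -> normal metabolizer (NM),
1 -> intermediate (IM), 2 -> poor (PM). TPMT and NUDT15 phenotypes combine
into a compound class, which maps onto the guideline's three initial-dose
recommendations for thiopurines:

========  ==========================================  ==================
class     definition                                   dosing category
========  ==========================================  ==================
NM_both   NM for both genes                            standard
IM_single IM for exactly one gene, NM for the other    consider_reduction
compound_IM  IM for both genes                         reduce
PM_any    PM for at least one gene                     reduce
========  ==========================================  ==================
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .count_reconstruct import round_half_up
from .model import GroupedCohort
from .star_caller import (
    NO_CALL,
    Diplotype,
    HaplotypeDefinition,
    call_cohort,
    load_allele_definitions,
)

PHENOTYPES = ("NM", "IM", "PM")
COMPOUND_CLASSES = ("NM_both", "IM_single", "compound_IM", "PM_any")
DOSING_CATEGORIES = ("standard", "consider_reduction", "reduce")


def functionality_map(
    definitions: Iterable[HaplotypeDefinition], gene: str
) -> dict[str, str]:
    return {d.star_name: d.function for d in definitions if d.gene == gene}


def phenotype_from_diplotype(
    diplotype: Diplotype, functionality: Mapping[str, str]
) -> str:
    """NM/IM/PM from the count of no-function haplotypes; no-calls pass
    through."""
    if not diplotype.is_call:
        return NO_CALL
    n_no_function = 0
    for star in diplotype.pair:
        if star not in functionality:
            raise KeyError(
                f"star allele {star} absent from the functionality table"
            )
        if functionality[star] == "no_function":
            n_no_function += 1
    return PHENOTYPES[n_no_function]


def compound_class(tpmt: str, nudt15: str) -> str:
    """Combine the two gene phenotypes into the compound class."""
    if NO_CALL in (tpmt, nudt15):
        return NO_CALL
    if "PM" in (tpmt, nudt15):
        return "PM_any"
    if tpmt == "IM" and nudt15 == "IM":
        return "compound_IM"
    if "IM" in (tpmt, nudt15):
        return "IM_single"
    return "NM_both"


def dosing_category(compound: str) -> str:
    """Map the compound class onto the three initial-dose recommendations."""
    if compound == NO_CALL:
        return NO_CALL
    return {
        "NM_both": "standard",
        "IM_single": "consider_reduction",
        "compound_IM": "reduce",
        "PM_any": "reduce",
    }[compound]


@dataclass
class PhenotypeAssignment:
    individual_id: str
    group: str
    tpmt_diplotype: Diplotype
    nudt15_diplotype: Diplotype
    tpmt_phenotype: str
    nudt15_phenotype: str
    compound: str
    category: str


def assign_phenotypes(
    cohort: GroupedCohort,
    definitions: Sequence[HaplotypeDefinition] | None = None,
    policy: str = "prefer_fewest_variant_haplotypes",
) -> list[PhenotypeAssignment]:
    """Run calling + phenotyping + dosing categorization for every
    individual."""
    if definitions is None:
        definitions = load_allele_definitions()
    calls = call_cohort(cohort, definitions, genes=("TPMT", "NUDT15"), policy=policy)
    func = {g: functionality_map(definitions, g) for g in ("TPMT", "NUDT15")}
    out = []
    for ind, dt, dn in zip(cohort.individuals, calls["TPMT"], calls["NUDT15"]):
        pt = phenotype_from_diplotype(dt, func["TPMT"])
        pn = phenotype_from_diplotype(dn, func["NUDT15"])
        comp = compound_class(pt, pn)
        out.append(
            PhenotypeAssignment(
                ind.individual_id, ind.group, dt, dn, pt, pn, comp,
                dosing_category(comp),
            )
        )
    return out


def _summary(
    assignments: Sequence[PhenotypeAssignment],
    attr: str,
    levels: Sequence[str],
    denominators: Mapping[str, int],
) -> pd.DataFrame:
    rows = []
    groups = list(dict.fromkeys(a.group for a in assignments))
    for group in groups:
        member_vals = [getattr(a, attr) for a in assignments if a.group == group]
        denom = denominators[group]
        for level in (*levels, NO_CALL):
            n = member_vals.count(level)
            if level == NO_CALL and n == 0:
                continue
            rows.append(
                {
                    "group": group,
                    attr: level,
                    "count": n,
                    "denominator": denom,
                    "percent": round_half_up(100.0 * n / denom, 1),
                }
            )
    return pd.DataFrame(rows)


def cohort_phenotype_report(
    cohort: GroupedCohort,
    definitions: Sequence[HaplotypeDefinition] | None = None,
    policy: str = "prefer_fewest_variant_haplotypes",
    denominator: str = "nominal",
) -> dict[str, pd.DataFrame]:
    """Per-group counts and percentages (1 dp) for TPMT phenotypes, NUDT15
    phenotypes, compound classes and dosing categories.

    ``denominator="nominal"`` uses the full group size (no-calls reported
    alongside); ``"called"`` restricts to individuals called at both genes.
    """
    assignments = assign_phenotypes(cohort, definitions, policy=policy)
    sizes = cohort.group_sizes()
    if denominator == "nominal":
        denoms = sizes
    elif denominator == "called":
        denoms = {
            g: sum(
                1 for a in assignments if a.group == g and a.compound != NO_CALL
            )
            for g in sizes
        }
    else:
        raise ValueError(f"unknown denominator mode: {denominator}")
    return {
        "tpmt_phenotype": _summary(assignments, "tpmt_phenotype", PHENOTYPES, denoms),
        "nudt15_phenotype": _summary(
            assignments, "nudt15_phenotype", PHENOTYPES, denoms
        ),
        "compound": _summary(assignments, "compound", COMPOUND_CLASSES, denoms),
        "category": _summary(assignments, "category", DOSING_CATEGORIES, denoms),
    }


def category_percent(
    report: dict[str, pd.DataFrame], group: str, category: str
) -> float:
    """Convenience lookup: dosing-category percentage for one group."""
    df = report["category"]
    row = df[(df["group"] == group) & (df["category"] == category)]
    if row.empty:
        return 0.0
    return float(row["percent"].iloc[0])
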