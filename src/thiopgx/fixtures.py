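"""Programmatic builder for the pinned three-cohort per-individual fixture.

The packaged file ``data/joint_cohort_fixture.tsv`` is a SYNTHETIC
reconstruction of the published three-cohort study (Yanomami, Munduruku,
Paiter-Surui; 90 individuals each), not the deposited raw data. It is
pinned so that the per-individual prose counts hold exactly:

* Yanomami: 3 NUDT15 *1/*3 carriers and 1 TPMT *1/*3A carrier, disjoint.
* Munduruku: 3 NUDT15 *1/*3, 1 NUDT15 *3/*3, 3 TPMT *1/*3A, all disjoint.
* Paiter-Surui: 2 NUDT15 *3/*3; 9 NUDT15 *1/*3 of which 4 co-occur with
  TPMT *1/*3A (the four compound IMs); 3 TPMT PMs (2 x *3A/*3A and
  1 x *3A/*3C); 23 further TPMT IM carriers (21 x *1/*3A, 2 x *1/*3B)
  disjoint from NUDT15 variant carriers; remainder wild-type.

Known, documented departures from the published marginal tables (the
per-individual truth is not recoverable from printed frequencies alone):
the Munduruku fixture holds 90 individuals although several printed rows
only fit a typed n of 92, and the Paiter TPMT heterozygote and *3A
chromosome counts fall slightly below the marginal reconstruction. The
dosing-category percentages, which the fixture exists to pin, are exact.
"""

from __future__ import annotations

from .model import PANEL, Genotype, GroupedCohort, Individual
from .star_caller import (
    HaplotypeDefinition,
    diplotype_to_genotypes,
    gene_loci,
    load_allele_definitions,
)


def _make_individual(
    iid: str,
    group: str,
    tpmt_pair: tuple[str, str],
    nudt15_pair: tuple[str, str],
    defs_by_star: dict[tuple[str, str], HaplotypeDefinition],
) -> Individual:
    genos: dict[str, Genotype] = {}
    for gene, pair in (("TPMT", tpmt_pair), ("NUDT15", nudt15_pair)):
        h1 = defs_by_star[(gene, pair[0])]
        h2 = defs_by_star[(gene, pair[1])]
        genos.update(diplotype_to_genotypes(h1, h2, gene_loci(gene)))
    return Individual(iid, group, genos)


# (count, TPMT pair, NUDT15 pair) blocks per group; order is the pinned
# individual order.
_BLOCKS: dict[str, list[tuple[int, tuple[str, str], tuple[str, str]]]] = {
    "Yanomami": [
        (3, ("*1", "*1"), ("*1", "*3")),
        (1, ("*1", "*3A"), ("*1", "*1")),
        (86, ("*1", "*1"), ("*1", "*1")),
    ],
    "Munduruku": [
        (3, ("*1", "*1"), ("*1", "*3")),
        (1, ("*1", "*1"), ("*3", "*3")),
        (3, ("*1", "*3A"), ("*1", "*1")),
        (83, ("*1", "*1"), ("*1", "*1")),
    ],
    "Paiter-Surui": [
        (2, ("*1", "*1"), ("*3", "*3")),
        (4, ("*1", "*3A"), ("*1", "*3")),
        (5, ("*1", "*1"), ("*1", "*3")),
        (2, ("*3A", "*3A"), ("*1", "*1")),
        (1, ("*3A", "*3C"), ("*1", "*1")),
        (21, ("*1", "*3A"), ("*1", "*1")),
        (2, ("*1", "*3B"), ("*1", "*1")),
        (53, ("*1", "*1"), ("*1", "*1")),
    ],
}

_PREFIX = {"Yanomami": "Y", "Munduruku": "M", "Paiter-Surui": "P"}


def build_joint_fixture() -> GroupedCohort:
    """Build the pinned 270-individual cohort from the block table above."""
    defs = load_allele_definitions()
    by_star = {(d.gene, d.star_name): d for d in defs}
    individuals: list[Individual] = []
    for group, blocks in _BLOCKS.items():
        i = 0
        for count, tpmt_pair, nudt15_pair in blocks:
            for _ in range(count):
                i += 1
                individuals.append(
                    _make_individual(
                        f"{_PREFIX[group]}{i:03d}", group, tpmt_pair, nudt15_pair, by_star
                    )
                )
        assert i == 90, f"{group}: fixture block counts sum to {i}, expected 90"
    return GroupedCohort(individuals, PANEL)
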