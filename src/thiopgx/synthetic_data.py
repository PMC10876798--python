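"""Synthetic grouped cohorts with known truth.

Simulation is haplotype-level: each individual draws two TPMT star-allele
haplotypes i.i.d. from the group's haplotype distribution and two NUDT15
alleles from the group's alt-allele frequency (random mating, hence HWE by
construction). Unphased genotypes are then derived from the allele
definition table, so linkage between the two TPMT sites is an emergent
property of the haplotype frequencies and EM-based LD estimates can be
checked against closed forms on the generating frequencies.

Randomness uses a single global seed with stream splitting: each group
(and each per-locus missingness mask) gets its own child generator keyed
by a CRC32 of the group/locus name, so adding a group or locus never
perturbs the draws of existing ones.

Defaults (``study_like_config``) emulate the three-cohort Amazonian study:
three groups of 90, TPMT *3A the dominant variant haplotype with *3B/*3C
rare and confined to one group, NUDT15 *3 at low frequency everywhere, and
no missingness (the published tables imply only a few percent dropout).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cpic_engine import compound_class, dosing_category
from .model import PANEL, Genotype, GroupedCohort, Individual, Locus
from .popgen_stats import fst_multigroup
from .star_caller import (
    HaplotypeDefinition,
    diplotype_to_genotypes,
    gene_definitions,
    gene_loci,
    load_allele_definitions,
)


@dataclass(frozen=True)
class GroupSpec:
    name: str
    n: int
    tpmt_hap_freqs: Mapping[str, float]
    nudt15_alt_freq: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        total = sum(self.tpmt_hap_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: TPMT haplotype frequencies sum to {total}, not 1"
            )
        if any(f < 0 or f > 1 for f in self.tpmt_hap_freqs.values()):
            raise ValueError(f"{self.name}: haplotype frequency outside [0, 1]")
        if not 0.0 <= self.nudt15_alt_freq <= 1.0:
            raise ValueError(f"{self.name}: NUDT15 alt frequency outside [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    groups: tuple[GroupSpec, ...]
    missingness: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missingness <= 1.0:
            raise ValueError("missingness must be a probability")


def study_like_config(seed: int = 0, missingness: float = 0.0) -> SimulationConfig:
    """The study conditions: three groups of 90 at the published haplotype
    frequencies (TPMT star frequencies and NUDT15 MAFs)."""
    return SimulationConfig(
        groups=(
            GroupSpec(
                "Yanomami", 90, {"*1": 0.994, "*3A": 0.006}, 0.017
            ),
            GroupSpec(
                "Munduruku", 90, {"*1": 0.984, "*3A": 0.016}, 0.027
            ),
            GroupSpec(
                "Paiter-Surui",
                90,
                {"*1": 0.803, "*3A": 0.180, "*3B": 0.011, "*3C": 0.006},
                0.072,
            ),
        ),
        missingness=missingness,
        seed=seed,
    )


def _stream(seed: int, *keys: str) -> np.random.Generator:
    """Named child stream of the global seed (CRC32-keyed, order-stable)."""
    spawn_key = tuple(zlib.crc32(k.encode()) for k in keys)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def simulate_cohort(
    config: SimulationConfig,
    definitions: Sequence[HaplotypeDefinition] | None = None,
    panel: Sequence[Locus] = PANEL,
) -> tuple[GroupedCohort, pd.DataFrame]:
    """Draw a cohort; return (observed cohort, latent truth table).

    The truth table holds the drawn haplotypes and the phenotypes/dosing
    categories they imply, independent of any calling.
    """
    if definitions is None:
        definitions = load_allele_definitions()
    by_star = {(d.gene, d.star_name): d for d in definitions}
    tpmt_defs = gene_definitions(definitions, "TPMT")
    tpmt_func = {d.star_name: d.function for d in tpmt_defs}
    tpmt_loci = gene_loci("TPMT", panel)
    nudt15_loci = gene_loci("NUDT15", panel)

    individuals: list[Individual] = []
    truth_rows: list[dict] = []
    for gi, spec in enumerate(config.groups):
        rng = _stream(config.seed, "haplotypes", spec.name)
        stars = list(spec.tpmt_hap_freqs)
        probs = np.array([spec.tpmt_hap_freqs[s] for s in stars])
        tpmt_draws = rng.choice(len(stars), size=(spec.n, 2), p=probs)
        nudt15_draws = rng.random((spec.n, 2)) < spec.nudt15_alt_freq

        for i in range(spec.n):
            iid = f"{spec.name}_{i + 1:05d}"
            t1, t2 = sorted(stars[k] for k in tpmt_draws[i])
            n_pair = tuple(sorted("*3" if a else "*1" for a in nudt15_draws[i]))
            genos = diplotype_to_genotypes(
                by_star[("TPMT", t1)], by_star[("TPMT", t2)], tpmt_loci
            )
            genos.update(
                diplotype_to_genotypes(
                    by_star[("NUDT15", n_pair[0])],
                    by_star[("NUDT15", n_pair[1])],
                    nudt15_loci,
                )
            )
            tpmt_nf = sum(1 for s in (t1, t2) if tpmt_func[s] == "no_function")
            nudt15_nf = sum(1 for s in n_pair if s == "*3")
            tpmt_ph = ("NM", "IM", "PM")[tpmt_nf]
            nudt15_ph = ("NM", "IM", "PM")[nudt15_nf]
            comp = compound_class(tpmt_ph, nudt15_ph)
            truth_rows.append(
                {
                    "individual_id": iid,
                    "group": spec.name,
                    "tpmt_hap1": t1,
                    "tpmt_hap2": t2,
                    "nudt15_hap1": n_pair[0],
                    "nudt15_hap2": n_pair[1],
                    "tpmt_phenotype": tpmt_ph,
                    "nudt15_phenotype": nudt15_ph,
                    "compound": comp,
                    "category": dosing_category(comp),
                }
            )
            individuals.append(Individual(iid, spec.name, genos))

        if config.missingness > 0:
            members = individuals[-spec.n:]
            for loc in panel:
                mrng = _stream(config.seed, "missing", spec.name, loc.id)
                mask = mrng.random(spec.n) < config.missingness
                for ind, miss in zip(members, mask):
                    if miss:
                        ind.genotypes[loc.id] = Genotype.MISSING

    return GroupedCohort(individuals, tuple(panel)), pd.DataFrame(truth_rows)


def ambiguity_error_rate(tpmt_hap_freqs: Mapping[str, float]) -> float:
    """Closed-form rate at which the *1/*3A disambiguation policy miscalls
    the haplotype pair of a rs1800460/rs1142345 double heterozygote: the
    conditional probability that the true pair is *3B/*3C.
    """
    f1 = tpmt_hap_freqs.get("*1", 0.0)
    f3a = tpmt_hap_freqs.get("*3A", 0.0)
    f3b = tpmt_hap_freqs.get("*3B", 0.0)
    f3c = tpmt_hap_freqs.get("*3C", 0.0)
    num = 2 * f3b * f3c
    den = 2 * f1 * f3a + 2 * f3b * f3c
    if den == 0:
        return 0.0
    return num / den


def drift_scenario(
    base_freq: float,
    target_fst: float,
    n_groups: int,
    rel_tol: float = 0.05,
    max_iter: int = 200,
) -> list[float]:
    """Per-group allele frequencies whose closed-form normalized FST hits a
    target — a drift-like divergence generator.

    Groups are spread symmetrically around ``base_freq`` (pattern
    linspace(-1, 1) scaled by s, clipped to [0, 1]); s is solved by
    bisection until FST is within ``rel_tol`` of the target.
    """
    if not 0.0 <= target_fst <= 0.25:
        raise ValueError("target_fst must lie in [0, 0.25]")
    if n_groups < 2:
        raise ValueError("need at least two groups")
    if not 0.0 < base_freq < 1.0:
        raise ValueError("base_freq must be strictly inside (0, 1)")
    pattern = np.linspace(-1.0, 1.0, n_groups)

    def freqs_at(s: float) -> np.ndarray:
        return np.clip(base_freq + s * pattern, 0.0, 1.0)

    def fst_at(s: float) -> float:
        f = freqs_at(s)
        return fst_multigroup({f"g{i}": v for i, v in enumerate(f)}).fst

    if target_fst == 0.0:
        return [base_freq] * n_groups

    lo, hi = 0.0, 1e-3
    it = 0
    while fst_at(hi) < target_fst:
        hi *= 2
        it += 1
        if hi > 2.0 or it > max_iter:
            raise ValueError(
                f"target FST {target_fst} unreachable from base {base_freq}"
            )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f = fst_at(mid)
        if abs(f - target_fst) <= rel_tol * target_fst:
            return list(freqs_at(mid))
        if f < target_fst:
            lo = mid
        else:
            hi = mid
    raise ValueError("bisection failed to reach target FST within tolerance")
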