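"""Star-allele diplotype calling."""

import itertools

import numpy as np
import pytest

from conftest import brute_force_pairs, study_config_at
from thiopgx.model import Genotype
from thiopgx.star_caller import (
    NO_CALL,
    call_diplotype,
    call_cohort,
    diplotype_to_genotypes,
    enumerate_consistent_pairs,
    gene_definitions,
    gene_loci,
    star_frequencies,
)
from thiopgx.synthetic_data import simulate_cohort

TPMT_LOCI = ("rs1800462", "rs1800460", "rs1142345")


def _tpmt_genos(d238=0, d460=0, d719=0):
    return {
        "rs1800462": Genotype.from_dosage(d238),
        "rs1800460": Genotype.from_dosage(d460),
        "rs1142345": Genotype.from_dosage(d719),
    }


def test_all_hom_ref_is_reference_diplotype(definitions):
    defs = gene_definitions(definitions, "TPMT")
    assert enumerate_consistent_pairs(_tpmt_genos(), defs, TPMT_LOCI) == [("*1", "*1")]


def test_double_het_has_two_candidates(definitions):
    defs = gene_definitions(definitions, "TPMT")
    pairs = enumerate_consistent_pairs(_tpmt_genos(d460=1, d719=1), defs, TPMT_LOCI)
    assert set(pairs) == {("*1", "*3A"), ("*3B", "*3C")}


def test_het_460_hom_719_unique(definitions):
    defs = gene_definitions(definitions, "TPMT")
    pairs = enumerate_consistent_pairs(_tpmt_genos(d460=1, d719=2), defs, TPMT_LOCI)
    assert pairs == [("*3A", "*3C")]


def test_enumeration_equals_brute_force_everywhere(definitions):
    """Caller enumeration matches a reference pair scan for every one of
    the 27 TPMT genotype combinations."""
    defs = gene_definitions(definitions, "TPMT")
    for d238, d460, d719 in itertools.product(range(3), repeat=3):
        genos = _tpmt_genos(d238, d460, d719)
        got = enumerate_consistent_pairs(genos, defs, TPMT_LOCI)
        want = brute_force_pairs(genos, defs, TPMT_LOCI)
        assert sorted(got) == sorted(want), (d238, d460, d719)


def test_missing_genotype_raises_in_enumeration(definitions):
    defs = gene_definitions(definitions, "TPMT")
    genos = _tpmt_genos()
    genos["rs1800460"] = Genotype.MISSING
    with pytest.raises(ValueError, match="missing genotype"):
        enumerate_consistent_pairs(genos, defs, TPMT_LOCI)


def test_call_double_het_resolved_by_policy(definitions):
    d = call_diplotype("i", _tpmt_genos(d460=1, d719=1), definitions, "TPMT")
    assert d.pair == ("*1", "*3A")
    assert d.ambiguous
    assert ("*3B", "*3C") in d.candidates


def test_call_em_frequency_policy_can_flip(definitions):
    freqs = {"*1": 0.05, "*3A": 0.05, "*3B": 0.5, "*3C": 0.4}
    d = call_diplotype(
        "i", _tpmt_genos(d460=1, d719=1), definitions, "TPMT",
        policy="em_frequency", hap_freqs=freqs,
    )
    assert d.pair == ("*3B", "*3C")
    assert d.ambiguous


def test_call_nudt15_never_ambiguous(definitions):
    d = call_diplotype(
        "i", {"rs116855232": Genotype.HET}, definitions, "NUDT15"
    )
    assert d.pair == ("*1", "*3") and not d.ambiguous


def test_call_hom_hom_unambiguous(definitions):
    d = call_diplotype("i", _tpmt_genos(d460=2, d719=2), definitions, "TPMT")
    assert d.pair == ("*3A", "*3A") and not d.ambiguous


def test_missing_gives_no_call(definitions):
    genos = _tpmt_genos()
    genos["rs1142345"] = Genotype.MISSING
    d = call_diplotype("i", genos, definitions, "TPMT")
    assert not d.is_call and d.hap1 == NO_CALL


def test_round_trip_every_tpmt_pair(definitions):
    """Synthesize genotypes from any pair, re-call: implied genotypes match
    the input, and the call is the original pair whenever unambiguous."""
    defs = gene_definitions(definitions, "TPMT")
    by_star = {d.star_name: d for d in defs}
    for h1, h2 in itertools.combinations_with_replacement(defs, 2):
        genos = diplotype_to_genotypes(h1, h2, TPMT_LOCI)
        call = call_diplotype("i", genos, definitions, "TPMT")
        implied = diplotype_to_genotypes(
            by_star[call.hap1], by_star[call.hap2], TPMT_LOCI
        )
        assert implied == genos
        if not call.ambiguous:
            assert call.pair == tuple(sorted((h1.star_name, h2.star_name)))


def test_double_het_candidates_differ_in_burden(definitions):
    """The double-het candidates are NOT phenotype-equivalent: *1/*3A
    carries one no-function haplotype (IM) and *3B/*3C carries two (PM).
    The default policy picks the lighter-burden pair, so its phenotype
    error rate equals its haplotype miscall rate (tested against the
    closed form in the simulator suite)."""
    func = {d.star_name: d.function for d in gene_definitions(definitions, "TPMT")}
    pairs = enumerate_consistent_pairs(
        _tpmt_genos(d460=1, d719=1), gene_definitions(definitions, "TPMT"), TPMT_LOCI
    )
    burden = {
        p: sum(1 for s in p if func[s] == "no_function") for p in pairs
    }
    assert set(burden.values()) == {1, 2}
    call = call_diplotype("i", _tpmt_genos(d460=1, d719=1), definitions, "TPMT")
    assert burden[call.pair] == 1


def test_star_frequencies_pinned_yanomami(definitions, joint_cohort):
    yan = joint_cohort.subset("Yanomami")
    calls = call_cohort(yan, definitions, genes=("TPMT",))
    group_of = {i.individual_id: i.group for i in yan.individuals}
    freqs = star_frequencies(calls["TPMT"], group_of)
    f = dict(zip(freqs["star"], freqs["freq"]))
    assert f["*1"] == 0.994
    assert f["*3A"] == 0.006


def test_star_frequencies_all_reference(definitions, joint_cohort):
    ref_only = [
        i for i in joint_cohort.individuals
        if all(g is Genotype.HOM_REF for g in i.genotypes.values())
    ]
    from thiopgx.model import GroupedCohort

    cohort = GroupedCohort(ref_only, joint_cohort.loci)
    calls = call_cohort(cohort, definitions, genes=("TPMT",))
    group_of = {i.individual_id: i.group for i in cohort.individuals}
    freqs = star_frequencies(calls["TPMT"], group_of)
    assert (freqs["freq"] == 1.0).all()
    assert set(freqs["star"]) == {"*1"}


def test_star_frequency_recovery_from_simulation(definitions):
    """Estimated star frequencies at n = 2000 fall within 3 SE of truth."""
    cohort, _ = simulate_cohort(study_config_at(2000, seed=5))
    paiter = cohort.subset("Paiter-Surui")
    calls = call_cohort(paiter, definitions, genes=("TPMT",))
    group_of = {i.individual_id: i.group for i in paiter.individuals}
    freqs = star_frequencies(calls["TPMT"], group_of)
    est = dict(zip(freqs["star"], freqs["count"] / freqs["n_chromosomes"]))
    truth = {"*1": 0.803, "*3A": 0.180, "*3B": 0.011, "*3C": 0.006}
    n_chrom = 2 * 2000
    for star, p in truth.items():
        se = np.sqrt(p * (1 - p) / n_chrom)
        assert abs(est.get(star, 0.0) - p) <= 3 * se + 1e-9, star
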