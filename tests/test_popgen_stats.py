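"""Frequencies, HWE, homogeneity/Cramér's V, FST, EM phasing and LD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency, chisquare

from conftest import em_mle_oracle, hwe_exact_oracle
from thiopgx.count_reconstruct import round_half_up
from thiopgx.model import GenotypeCounts
from thiopgx.popgen_stats import (
    allele_freq,
    em_phase_from_genotype_classes,
    fst_multigroup,
    homogeneity_test,
    hwe_test,
    ld_from_hap_freqs,
)

# ---------------------------------------------------------------------------
# allele frequencies


@pytest.mark.parametrize(
    "counts, expected_freq_3dp",
    [
        ((79, 9, 2), 0.072),  # 13/180
        ((90, 0, 0), 0.0),
        ((57, 29, 2), 0.188),  # 33/176
        ((57, 28, 3), 0.193),  # 34/176
    ],
)
def test_allele_freq(counts, expected_freq_3dp):
    c = GenotypeCounts("g", "l", *counts)
    freq, alt, total = allele_freq(c)
    assert round_half_up(freq, 3) == expected_freq_3dp
    assert alt == counts[1] + 2 * counts[2]
    assert total == 2 * sum(counts)


def test_allele_freq_excludes_missing_and_rejects_untyped():
    c = GenotypeCounts("g", "l", 8, 2, 0, n_missing=10)
    assert allele_freq(c)[0] == 2 / 20
    with pytest.raises(ValueError):
        allele_freq(GenotypeCounts("g", "l", 0, 0, 0, n_missing=5))


# ---------------------------------------------------------------------------
# HWE


def test_hwe_identity_at_exact_proportions():
    # freq 0.1, expected counts exactly (81, 18, 1)
    r = hwe_test(GenotypeCounts("g", "l", 81, 18, 1))
    assert r.chi2 == pytest.approx(0.0, abs=1e-12)
    assert r.p_chi2 == pytest.approx(1.0)


def test_hwe_near_fixation_small_chi2():
    r = hwe_test(GenotypeCounts("g", "l", 89, 1, 0))
    assert r.chi2 == pytest.approx(0.003, abs=1e-3)
    assert r.p_chi2 == pytest.approx(0.96, abs=0.01)
    assert r.p_exact == 1.0  # the single-het configuration is the modal one


def test_hwe_monomorphic_convention():
    r = hwe_test(GenotypeCounts("g", "l", 90, 0, 0))
    assert (r.chi2, r.p_chi2, r.p_exact) == (0.0, 1.0, 1.0)


def test_hwe_exact_equals_enumeration_oracle_all_small_instances():
    """The exact conditional p matches an independent rational-arithmetic
    enumeration for every genotype configuration with n <= 30."""
    for n in range(1, 31):
        for hom_alt in range(n + 1):
            for het in range(n + 1 - hom_alt):
                hom_ref = n - hom_alt - het
                r = hwe_test(GenotypeCounts("g", "l", hom_ref, het, hom_alt))
                rare, common = sorted((hom_alt, hom_ref))
                expected = hwe_exact_oracle(het, rare, common)
                assert r.p_exact == pytest.approx(expected, rel=1e-9), (
                    hom_ref,
                    het,
                    hom_alt,
                )


@given(
    st.integers(0, 200), st.integers(0, 200), st.integers(0, 200)
)
@settings(max_examples=100, derandomize=True, deadline=None)
def test_hwe_chi2_matches_scipy_goodness_of_fit(a, b, c):
    n = a + b + c
    if n == 0:
        return
    counts = GenotypeCounts("g", "l", a, b, c)
    q = (b + 2 * c) / (2 * n)
    if q in (0.0, 1.0):
        return
    p = 1 - q
    expected = np.array([p * p, 2 * p * q, q * q]) * n
    stat, _ = chisquare([a, b, c], f_exp=expected)
    r = hwe_test(counts)
    assert r.chi2 == pytest.approx(stat, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# homogeneity + Cramér's V


def test_identical_rows_give_zero():
    r = homogeneity_test([[10, 5, 1], [10, 5, 1]])
    assert r.chi2 == pytest.approx(0.0, abs=1e-12)
    assert r.v == pytest.approx(0.0, abs=1e-9)
    assert r.magnitude == "negligible"


def test_perfect_association_2x2():
    r = homogeneity_test([[10, 0], [0, 10]])
    assert r.chi2 == pytest.approx(20.0)
    assert r.df_p == 1 and r.df_v == 1 and r.n == 20
    assert r.v == pytest.approx(1.0)
    assert r.magnitude == "large"


def test_zero_marginal_rejected():
    with pytest.raises(ValueError, match="drop the empty category"):
        homogeneity_test([[3, 0], [5, 0]])


@given(
    st.lists(
        st.lists(st.integers(1, 50), min_size=2, max_size=4),
        min_size=2,
        max_size=4,
    ).filter(lambda t: len({len(r) for r in t}) == 1)
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_chi2_and_p_match_scipy_contingency(table):
    r = homogeneity_test(table)
    chi2, p, df, _ = chi2_contingency(np.array(table), correction=False)
    assert r.chi2 == pytest.approx(chi2, rel=1e-9)
    assert r.p == pytest.approx(p, rel=1e-6, abs=1e-12)
    assert r.df_p == df


@pytest.mark.parametrize("k", [2, 5, 10])
def test_v_invariant_under_cell_scaling(k):
    table = np.array([[12, 3, 5], [4, 9, 7], [6, 6, 1]])
    r1 = homogeneity_test(table)
    rk = homogeneity_test(k * table)
    assert rk.chi2 == pytest.approx(k * r1.chi2, rel=1e-9)
    assert rk.v == pytest.approx(r1.v, rel=1e-9)


# ---------------------------------------------------------------------------
# FST


def test_fst_published_values():
    assert round_half_up(
        fst_multigroup({"Y": 0.017, "M": 0.027, "P": 0.072}).fst, 2
    ) == 0.02
    r = fst_multigroup({"Y": 0.006, "M": 0.016, "P": 0.193})
    assert round_half_up(r.fst, 2) == 0.11
    assert r.interpretation == "moderate"
    assert r.ht == pytest.approx(0.13306, abs=5e-6)
    assert r.hs == pytest.approx(0.11831, abs=5e-6)


def test_fst_zero_when_equal_and_degenerate_when_fixed():
    assert fst_multigroup({"a": 0.3, "b": 0.3, "c": 0.3}).fst == pytest.approx(0.0)
    r = fst_multigroup({"a": 0.0, "b": 0.0})
    assert r.fst == 0.0 and r.degenerate


@given(
    st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
    st.permutations(range(6)),
)
@settings(max_examples=60, derandomize=True, deadline=None)
def test_fst_invariances(freqs, perm):
    labels = [f"g{i}" for i in range(len(freqs))]
    base = fst_multigroup(dict(zip(labels, freqs))).fst
    order = [i for i in perm if i < len(freqs)]
    shuffled = fst_multigroup(
        {labels[i]: freqs[i] for i in order}
    ).fst
    flipped = fst_multigroup(
        {l: 1 - f for l, f in zip(labels, freqs)}
    ).fst
    assert shuffled == pytest.approx(base, rel=1e-12, abs=1e-12)
    assert flipped == pytest.approx(base, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# EM phasing and LD


def test_complete_ld_no_ambiguity():
    # only ref-ref and alt-alt haplotypes present: 4x hom-hom, 4x double het
    g = np.zeros((3, 3), dtype=int)
    g[0, 0] = 10
    g[2, 2] = 5
    g[1, 1] = 4
    r = em_phase_from_genotype_classes(g)
    assert r.converged
    assert r.d_prime == pytest.approx(1.0, abs=1e-6)
    assert r.r2 == pytest.approx(1.0, abs=1e-6)


def test_monomorphic_locus_rejected():
    g = np.zeros((3, 3), dtype=int)
    g[0, 0] = 10
    with pytest.raises(ValueError, match="monomorphic"):
        em_phase_from_genotype_classes(g)


def _random_tables(n_tables=40, max_n=20, seed=2024):
    rng = np.random.default_rng(seed)
    tables = []
    while len(tables) < n_tables:
        n = rng.integers(2, max_n + 1)
        flat = rng.multinomial(n, np.full(9, 1 / 9))
        g = flat.reshape(3, 3)
        dose_a = (g.sum(axis=1) * np.arange(3)).sum() / (2 * n)
        dose_b = (g.sum(axis=0) * np.arange(3)).sum() / (2 * n)
        if dose_a in (0.0, 1.0) or dose_b in (0.0, 1.0):
            continue
        tables.append(g)
    return tables


@pytest.mark.parametrize("g", _random_tables(), ids=lambda g: str(g.sum()))
def test_em_matches_brute_force_mle_small_cohorts(g):
    """EM haplotype frequencies agree with direct 1-D likelihood
    maximization (the margins are fixed by the data) to 1e-6."""
    r = em_phase_from_genotype_classes(g)
    oracle = em_mle_oracle(g)
    est = np.array(
        [[r.hap_freqs["00"], r.hap_freqs["01"]], [r.hap_freqs["10"], r.hap_freqs["11"]]]
    )
    assert np.abs(est - oracle).max() < 1e-6
    # EM guarantee: the log-likelihood never decreases
    trace = np.array(r.loglik_trace)
    assert (np.diff(trace) >= -1e-9).all()
    assert abs(sum(r.hap_freqs.values()) - 1) < 1e-12


def test_independent_loci_ld_vanishes():
    """At linkage equilibrium (pA = pB = 0.3, n = 5000) the estimated R²
    averages to ~1/n; across 20 seeded replicates the mean stays < 0.01."""
    rng = np.random.default_rng(77)
    hap_p = np.array([0.49, 0.21, 0.21, 0.09])  # independent, pA = pB = 0.3
    r2s, dps = [], []
    for _ in range(20):
        haps = rng.multinomial(2 * 5000, hap_p)
        # pair haplotypes randomly into genotypes
        pool = np.repeat(np.arange(4), haps)
        rng.shuffle(pool)
        g = np.zeros((3, 3), dtype=int)
        for h1, h2 in pool.reshape(-1, 2):
            g[h1 // 2 + h2 // 2, h1 % 2 + h2 % 2] += 1
        r = em_phase_from_genotype_classes(g)
        r2s.append(r.r2)
        dps.append(r.d_prime)
    assert np.mean(r2s) < 0.01
    assert np.mean(dps) < 0.2


def test_ld_closed_form_sanity():
    d, dp, r2 = ld_from_hap_freqs(0.5, 0.0, 0.0, 0.5)
    assert (d, dp, r2) == (pytest.approx(0.25), pytest.approx(1.0), pytest.approx(1.0))
    with pytest.raises(ValueError):
        ld_from_hap_freqs(0.5, 0.5, 0.0, 0.0)  # locus A monomorphic
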