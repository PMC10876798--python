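"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from thiopgx.genotype_io import load_joint_fixture
from thiopgx.star_caller import load_allele_definitions
from thiopgx.synthetic_data import GroupSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def definitions():
    return load_allele_definitions()


@pytest.fixture(scope="session")
def joint_cohort():
    return load_joint_fixture()


STUDY_FREQS = {
    "Yanomami": ({"*1": 0.994, "*3A": 0.006}, 0.017),
    "Munduruku": ({"*1": 0.984, "*3A": 0.016}, 0.027),
    "Paiter-Surui": ({"*1": 0.803, "*3A": 0.180, "*3B": 0.011, "*3C": 0.006}, 0.072),
}


def study_config_at(n: int, seed: int, missingness: float = 0.0) -> SimulationConfig:
    groups = tuple(
        GroupSpec(name, n, haps, alt) for name, (haps, alt) in STUDY_FREQS.items()
    )
    return SimulationConfig(groups=groups, missingness=missingness, seed=seed)


@pytest.fixture(scope="session")
def big_sim():
    """One large draw (50k per group) at the study frequencies, shared by the
    consistency checks that need tight sampling error."""
    return simulate_cohort(study_config_at(50_000, seed=1))


# ---------------------------------------------------------------------------
# Independent oracles


def hwe_exact_oracle(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact HWE p by direct rational enumeration (exact integer
    combinatorics, no logs): P(h | n, n_rare) proportional to
    C(n; hr, h, hc) * 2^h, normalized over admissible heterozygote counts.
    """
    n = n_het + n_hom_rare + n_hom_common
    n_rare = 2 * n_hom_rare + n_het
    if n == 0:
        return 1.0
    weights: dict[int, Fraction] = {}
    for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2):
        hr = (n_rare - h) // 2
        hc = n - h - hr
        w = Fraction(
            comb(n, hr) * comb(n - hr, h) * 2**h
        )
        weights[h] = w
    total = sum(weights.values())
    probs = {h: w / total for h, w in weights.items()}
    p_obs = probs[n_het]
    return float(sum(p for p in probs.values() if p <= p_obs))


def em_mle_oracle(g: np.ndarray) -> np.ndarray:
    """Brute-force two-locus haplotype MLE.

    The likelihood's allele-frequency margins equal the observed dosage
    means, leaving one free parameter: the cis haplotype frequency p11.
    Maximize the exact multinomial log-likelihood over its feasible
    interval by dense grid + bounded scalar refinement.
    """
    g = np.asarray(g, dtype=float)
    n = g.sum()
    pa = (g.sum(axis=1) * np.arange(3)).sum() / (2 * n)
    pb = (g.sum(axis=0) * np.arange(3)).sum() / (2 * n)

    def negll(p11: float) -> float:
        p10 = pa - p11
        p01 = pb - p11
        p00 = 1 - pa - pb + p11
        p = np.array([[p00, p01], [p10, p11]])
        if (p < -1e-12).any():
            return np.inf
        p = np.clip(p, 1e-300, None)
        probs = {
            (0, 0): p[0, 0] ** 2,
            (0, 1): 2 * p[0, 0] * p[0, 1],
            (0, 2): p[0, 1] ** 2,
            (1, 0): 2 * p[0, 0] * p[1, 0],
            (1, 2): 2 * p[0, 1] * p[1, 1],
            (2, 0): p[1, 0] ** 2,
            (2, 1): 2 * p[1, 0] * p[1, 1],
            (2, 2): p[1, 1] ** 2,
            (1, 1): 2 * p[0, 0] * p[1, 1] + 2 * p[0, 1] * p[1, 0],
        }
        return -sum(
            g[i, j] * np.log(max(probs[(i, j)], 1e-300))
            for i in range(3)
            for j in range(3)
            if g[i, j] > 0
        )

    lo = max(0.0, pa + pb - 1.0)
    hi = min(pa, pb)
    grid = np.linspace(lo, hi, 2001)
    vals = [negll(x) for x in grid]
    k = int(np.argmin(vals))
    a, b = grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]
    if a == b:
        p11 = grid[k]
    else:
        res = minimize_scalar(
            negll, bounds=(a, b), method="bounded", options={"xatol": 1e-12}
        )
        p11 = res.x if res.fun <= vals[k] else grid[k]
    return np.array(
        [[1 - pa - pb + p11, pb - p11], [pa - p11, p11]]
    )


def brute_force_pairs(genotypes, defs, loci):
    """Reference pair enumeration: check every unordered pair of defined
    haplotypes against observed dosages, written independently of the
    caller."""
    observed = {lid: genotypes[lid].dosage for lid in loci}
    out = []
    for i, h1 in enumerate(defs):
        for h2 in defs[i:]:
            ok = True
            for lid in loci:
                implied = (lid in h1.variant_set) + (lid in h2.variant_set)
                if implied != observed[lid]:
                    ok = False
                    break
            if ok:
                out.append((h1.star_name, h2.star_name))
    return out
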