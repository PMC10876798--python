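"""Population-genetic statistics for grouped biallelic genotype counts.

Covers the full statistical toolkit of a small multi-cohort pharmacogene
survey: allele frequencies, Hardy-Weinberg tests (asymptotic chi-square and
the exact conditional test), chi-square homogeneity with Cramér's V effect
size, the multi-group fixation index from heterozygosities (GST form), and
two-locus haplotype phasing by EM with the standard LD summaries D, D′, R².
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .model import Genotype, GenotypeCounts, GroupedCohort

# Cohen-style effect-size bands for Cramér's V. The cut points are the
# conventional ones; they are parameters of homogeneity_test, and reports
# always print the numeric V alongside the label.
V_MAGNITUDE_BANDS: tuple[tuple[float, str], ...] = (
    (0.1, "negligible"),
    (0.3, "small"),
    (0.5, "intermediate"),
    (math.inf, "large"),
)

# Wright's qualitative interpretation bands for FST.
FST_BANDS: tuple[tuple[float, str], ...] = (
    (0.05, "little"),
    (0.15, "moderate"),
    (0.25, "large"),
    (math.inf, "very large"),
)


def _band_label(x: float, bands: Sequence[tuple[float, str]]) -> str:
    for upper, label in bands:
        if x < upper:
            return label
    return bands[-1][1]


def allele_freq(counts: GenotypeCounts) -> tuple[float, int, int]:
    """Alt-allele frequency with the integer allele counts behind it.

    Returns ``(freq, n_alt_alleles, n_alleles)``; missing individuals are
    excluded from the denominator.
    """
    n = counts.n_typed
    if n == 0:
        raise ValueError(f"{counts.group}/{counts.locus_id}: no typed individuals")
    alt = counts.alt_allele_count
    return alt / (2 * n), alt, 2 * n


# ---------------------------------------------------------------------------
# Hardy-Weinberg


@dataclass(frozen=True)
class HweResult:
    group: str
    locus_id: str
    chi2: float
    df: int
    p_chi2: float
    p_exact: float
    n_typed: int


def hwe_exact_p(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact conditional HWE test for a biallelic site.

    Enumerates the distribution of the heterozygote count conditional on
    the typed sample size and the minor-allele count, and sums the
    probabilities of all configurations no more probable than the observed
    one (no mid-p adjustment).
    """
    n = n_het + n_hom_rare + n_hom_common
    n_rare = 2 * n_hom_rare + n_het
    if n == 0:
        return 1.0
    # heterozygote count has the parity of the rare-allele count
    het_values = [h for h in range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)]
    log_probs = []
    for h in het_values:
        hr = (n_rare - h) // 2
        hc = n - h - hr
        lp = (
            h * math.log(2)
            + math.lgamma(n + 1)
            - math.lgamma(hr + 1)
            - math.lgamma(h + 1)
            - math.lgamma(hc + 1)
            + math.lgamma(n_rare + 1)
            + math.lgamma(2 * n - n_rare + 1)
            - math.lgamma(2 * n + 1)
        )
        log_probs.append(lp)
    probs = np.exp(log_probs - np.max(log_probs))
    probs /= probs.sum()
    p_obs = probs[het_values.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(counts: GenotypeCounts) -> HweResult:
    """Chi-square (df=1, no continuity correction) and exact HWE tests.

    A monomorphic locus deviates from nothing: chi2 = 0, p = 1 by
    convention.
    """
    n = counts.n_typed
    if n < 1:
        raise ValueError("hwe_test needs at least one typed individual")
    q = counts.alt_allele_count / (2 * n)
    obs = np.array(counts.counts, dtype=float)
    if q == 0.0 or q == 1.0:
        return HweResult(counts.group, counts.locus_id, 0.0, 1, 1.0, 1.0, n)
    p = 1.0 - q
    exp = np.array([p * p, 2 * p * q, q * q]) * n
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    # orient hom classes as rare/common for the exact test
    if counts.n_hom_alt <= counts.n_hom_ref:
        p_exact = hwe_exact_p(counts.n_het, counts.n_hom_alt, counts.n_hom_ref)
    else:
        p_exact = hwe_exact_p(counts.n_het, counts.n_hom_ref, counts.n_hom_alt)
    return HweResult(counts.group, counts.locus_id, chi2, 1, p_chi2, p_exact, n)


# ---------------------------------------------------------------------------
# Homogeneity + Cramér's V


@dataclass(frozen=True)
class HomogeneityResult:
    table: tuple[tuple[int, ...], ...]
    chi2: float
    df_p: int
    p: float
    df_v: int
    v: float
    n: int
    magnitude: str


def homogeneity_test(
    table: Sequence[Sequence[int]] | np.ndarray,
    magnitude_bands: Sequence[tuple[float, str]] = V_MAGNITUDE_BANDS,
) -> HomogeneityResult:
    """Pearson chi-square homogeneity test with Cramér's V.

    V = sqrt(X² / (n · min(r−1, c−1))); the p-value uses the usual
    (r−1)(c−1) degrees of freedom. Empty rows or columns must be dropped by
    the caller — a zero marginal makes the expected counts degenerate.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.min() < 0:
        raise ValueError("table must be a 2-D non-negative matrix")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        raise ValueError(
            "zero row/column marginal; drop the empty category before testing"
        )
    n = t.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((t - expected) ** 2 / expected).sum())
    r, c = t.shape
    df_p = (r - 1) * (c - 1)
    df_v = min(r - 1, c - 1)
    p = float(stats.chi2.sf(chi2, df=df_p)) if df_p > 0 else 1.0
    v = math.sqrt(chi2 / (n * df_v)) if df_v > 0 else 0.0
    return HomogeneityResult(
        tuple(tuple(int(x) for x in rw) for rw in np.asarray(table)),
        chi2,
        df_p,
        p,
        df_v,
        v,
        int(n),
        _band_label(v, magnitude_bands),
    )


# ---------------------------------------------------------------------------
# Multi-group FST


@dataclass(frozen=True)
class FstResult:
    locus_id: str
    group_freqs: dict[str, float]
    hs: float
    ht: float
    fst_raw: float
    fst: float
    interpretation: str
    degenerate: bool = False


def fst_multigroup(
    freqs: Mapping[str, float], locus_id: str = ""
) -> FstResult:
    """Fixation index across groups from alt-allele frequencies.

    HS is the unweighted mean within-group expected heterozygosity
    2p(1−p); HT is the expected heterozygosity at the unweighted mean
    frequency. Both the raw difference HT − HS and the normalized
    (HT − HS)/HT (the GST form) are reported; the normalized value is the
    headline FST. When HT = 0 (all groups fixed for the same allele) FST
    is 0 by convention and the result is flagged degenerate.
    """
    if len(freqs) < 2:
        raise ValueError("fst_multigroup needs at least two groups")
    p = np.array(list(freqs.values()), dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    hs = float(np.mean(2 * p * (1 - p)))
    pbar = float(p.mean())
    ht = 2 * pbar * (1 - pbar)
    raw = ht - hs
    if ht == 0.0:
        return FstResult(locus_id, dict(freqs), hs, ht, 0.0, 0.0,
                         _band_label(0.0, FST_BANDS), degenerate=True)
    fst = raw / ht
    return FstResult(
        locus_id, dict(freqs), hs, ht, raw, fst, _band_label(fst, FST_BANDS)
    )


# ---------------------------------------------------------------------------
# Two-locus EM phasing and LD


@dataclass(frozen=True)
class LdResult:
    locus_pair: tuple[str, str]
    hap_freqs: dict[str, float]  # keys "00", "01", "10", "11" (ref/alt at A,B)
    d: float
    d_prime: float
    r2: float
    n_chromosomes: int
    em_iterations: int
    converged: bool
    loglik_trace: tuple[float, ...] = field(default=())


def ld_from_hap_freqs(p00: float, p01: float, p10: float, p11: float) -> tuple[float, float, float]:
    """Closed-form D, D′, R² from the four haplotype frequencies."""
    pa = p10 + p11  # alt at locus A
    pb = p01 + p11  # alt at locus B
    d = p11 - pa * pb
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic locus")
    if d > 0:
        dmax = min(pa * (1 - pb), pb * (1 - pa))
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    d_prime = abs(d) / dmax if dmax > 0 else 0.0
    r2 = d * d / (pa * (1 - pa) * pb * (1 - pb))
    return d, d_prime, r2


def _genotype_class_counts(
    cohort: GroupedCohort, locus_a: str, locus_b: str
) -> np.ndarray:
    counts = np.zeros((3, 3), dtype=int)
    for ind in cohort.individuals:
        da = ind.genotype(locus_a).dosage
        db = ind.genotype(locus_b).dosage
        if da is None or db is None:
            continue  # pairwise exclusion of missing data
        counts[da, db] += 1
    return counts


def em_phase_two_locus(
    cohort: GroupedCohort,
    locus_a: str,
    locus_b: str,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdResult:
    """EM haplotype-frequency estimation over the 9 unphased two-locus
    genotype classes, followed by LD summaries.

    Only the double heterozygote carries latent phase; all other classes
    contribute fixed haplotype counts. Iteration stops when every haplotype
    frequency moves by less than ``tol``. The log-likelihood at each
    iteration is recorded (it is non-decreasing, an EM guarantee that the
    tests assert).
    """
    g = _genotype_class_counts(cohort, locus_a, locus_b)
    return em_phase_from_genotype_classes(
        g, (locus_a, locus_b), tol=tol, max_iter=max_iter
    )


def em_phase_from_genotype_classes(
    g: np.ndarray,
    locus_pair: tuple[str, str] = ("A", "B"),
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> LdResult:
    """EM on a 3x3 matrix of two-locus genotype-class counts (dosage A x
    dosage B)."""
    g = np.asarray(g, dtype=float)
    n = g.sum()
    if n == 0:
        raise ValueError("no individuals typed at both loci")
    dose_a = (g.sum(axis=1) * np.arange(3)).sum() / (2 * n)
    dose_b = (g.sum(axis=0) * np.arange(3)).sum() / (2 * n)
    if dose_a in (0.0, 1.0) or dose_b in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic locus")

    # fixed haplotype contributions: hap (x, y) counts from genotype (i, j)
    # for every class except the double het (1, 1)
    def fixed_hap_counts() -> np.ndarray:
        h = np.zeros((2, 2))
        for i in range(3):
            for j in range(3):
                if (i, j) == (1, 1) or g[i, j] == 0:
                    continue
                # split dosages into two haplotypes; unique for non-double-hets
                a_alleles = [1, 1] if i == 2 else ([0, 1] if i == 1 else [0, 0])
                b_alleles = [1, 1] if j == 2 else ([0, 1] if j == 1 else [0, 0])
                if i == 1:  # het at A, hom at B: both pairings identical
                    h[0, b_alleles[0]] += g[i, j]
                    h[1, b_alleles[1]] += g[i, j]
                elif j == 1:
                    h[a_alleles[0], 0] += g[i, j]
                    h[a_alleles[1], 1] += g[i, j]
                else:
                    h[a_alleles[0], b_alleles[0]] += g[i, j]
                    h[a_alleles[1], b_alleles[1]] += g[i, j]
        return h

    fixed = fixed_hap_counts()
    n_dh = g[1, 1]

    # initialize at linkage equilibrium
    pa, pb = dose_a, dose_b
    p = np.array(
        [[(1 - pa) * (1 - pb), (1 - pa) * pb], [pa * (1 - pb), pa * pb]]
    )

    def loglik(p: np.ndarray) -> float:
        ll = 0.0
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
        for (i, j), pr in probs.items():
            if g[i, j] > 0:
                ll += g[i, j] * math.log(max(pr, 1e-300))
        return ll

    trace = [loglik(p)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: expected phase of double heterozygotes
        cis = p[0, 0] * p[1, 1]
        trans = p[0, 1] * p[1, 0]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        h = fixed.copy()
        h[0, 0] += n_dh * w
        h[1, 1] += n_dh * w
        h[0, 1] += n_dh * (1 - w)
        h[1, 0] += n_dh * (1 - w)
        # M step
        p_new = h / (2 * n)
        delta = np.abs(p_new - p).max()
        p = p_new
        trace.append(loglik(p))
        if delta < tol:
            converged = True
            break

    d, d_prime, r2 = ld_from_hap_freqs(p[0, 0], p[0, 1], p[1, 0], p[1, 1])
    return LdResult(
        locus_pair,
        {"00": p[0, 0], "01": p[0, 1], "10": p[1, 0], "11": p[1, 1]},
        d,
        d_prime,
        r2,
        int(2 * n),
        it,
        converged,
        tuple(trace),
    )


def format_p(p: float) -> str:
    """Report p-values to 4 decimals; below 1e-4 print "<0.0001"."""
    if p < 1e-4:
        return "<0.0001"
    return f"{p:.4f}"
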