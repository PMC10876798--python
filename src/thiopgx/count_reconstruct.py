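"""Recover integer genotype counts from rounded published frequency tables.

Population reports often print genotype-class proportions and MAFs to three
decimals without the underlying counts. For the small cohorts handled here
(n <= 200) the inverse problem is solvable by exhaustive search: enumerate
every typed sample size n in a window around the nominal cohort size and
every integer triple (hom_ref, het, hom_alt) summing to n, and keep the
triple whose rounded proportions best reproduce the printed row.

The search deliberately allows n != nominal: rows printed from cohorts with
undisclosed genotyping dropout are only consistent with a smaller (or, with
overcounts, larger) denominator, and the solver surfaces that rather than
forcing n.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .model import FrequencyRow, GenotypeCounts


def round_half_up(x: float, k: int) -> float:
    """Round ``x`` to ``k`` decimals, halves away from zero (0.1875 -> 0.188).

    Printed tables in this field use commercial rounding, not banker's
    rounding, so Python's built-in round() is not a substitute.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    q = Decimal(1).scaleb(-k)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReconstructionResult:
    group: str
    locus_id: str
    n_typed: int
    counts: tuple[int, int, int]
    residual: float
    unique: bool

    def to_genotype_counts(self, n_nominal: int | None = None) -> GenotypeCounts:
        """Package the solution, attributing any shortfall vs the nominal
        cohort size to missing genotypes."""
        missing = max(n_nominal - self.n_typed, 0) if n_nominal else 0
        return GenotypeCounts(
            self.group, self.locus_id, *self.counts, n_missing=missing
        )


def _round3_ratio(num: int, den: int) -> float:
    """round_half_up(num/den, 3) for non-negative integers, exactly."""
    return ((2000 * num + den) // (2 * den)) / 1000.0


def _row_residual(counts: tuple[int, int, int], n: int, printed: FrequencyRow) -> float:
    """Max absolute difference between printed values and the rounded
    proportions implied by integer counts, over the three genotype classes
    and the MAF. Integer arithmetic, so a residual of exactly 0.0 means every
    implied proportion reproduces the printed value at 3 decimals."""
    implied = [_round3_ratio(c, n) for c in counts]
    maf = _round3_ratio(counts[1] + 2 * counts[2], 2 * n)
    diffs = [abs(a - b) for a, b in zip(implied, printed.proportions)]
    diffs.append(abs(maf - printed.maf))
    return max(diffs)


def reconstruct_counts(
    printed: FrequencyRow,
    n_range: range | tuple[int, int],
    n_nominal: int | None = None,
) -> ReconstructionResult:
    """Exhaustively search typed sample sizes and integer genotype triples.

    Parameters
    ----------
    printed
        One published row: three genotype proportions and the MAF, each at
        3 decimals.
    n_range
        Typed sample sizes to search, as a ``range`` or an inclusive
        ``(lo, hi)`` pair; must lie within [1, 200].
    n_nominal
        The stated cohort size, used only for tie-breaking (prefer the n
        closest to nominal, then the smallest n). Defaults to the midpoint
        of ``n_range``.

    The optimum minimizes the residual lexicographically: first the max
    rounding discrepancy over (three proportions, MAF), then |n - nominal|,
    then n. ``unique`` reports whether a different count triple achieves the
    same residual anywhere in the searched range.
    """
    if isinstance(n_range, tuple):
        n_values = range(n_range[0], n_range[1] + 1)
    else:
        n_values = n_range
    n_values = [n for n in n_values if 1 <= n <= 200]
    if not n_values:
        raise ValueError("n_range is empty or outside [1, 200]")
    if n_nominal is None:
        n_nominal = (min(n_values) + max(n_values)) // 2

    best_key: tuple[float, int, int] | None = None
    best: ReconstructionResult | None = None
    ties: set[tuple[int, int, int]] = set()

    for n in n_values:
        for hom_ref in range(n + 1):
            for het in range(n + 1 - hom_ref):
                counts = (hom_ref, het, n - hom_ref - het)
                res = _row_residual(counts, n, printed)
                key = (res, abs(n - n_nominal), n)
                if best_key is None or res < best_key[0]:
                    best_key = key
                    best = ReconstructionResult(
                        printed.group, printed.locus_id, n, counts, res, True
                    )
                    ties = {counts}
                elif res == best_key[0]:
                    ties.add(counts)
                    if key < best_key:
                        best_key = key
                        best = ReconstructionResult(
                            printed.group, printed.locus_id, n, counts, res, True
                        )

    assert best is not None
    if len(ties) > 1:
        best = ReconstructionResult(
            best.group, best.locus_id, best.n_typed, best.counts, best.residual, False
        )
    return best


def reconstruct_table(
    rows: list[FrequencyRow],
    n_nominal: int = 90,
    window: int = 5,
) -> list[ReconstructionResult]:
    """Reconstruct every row of a published table with a shared n window
    (nominal +/- window)."""
    lo, hi = max(1, n_nominal - window), min(200, n_nominal + window)
    return [reconstruct_counts(r, (lo, hi), n_nominal=n_nominal) for r in rows]
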