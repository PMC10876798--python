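# Methods

## Data model and panel

The unit of analysis is a grouped cohort: per-individual unphased
genotypes at a fixed four-SNP panel (NUDT15 rs116855232; TPMT rs1800462,
rs1800460, rs1142345) with a group label. Genotypes are stored as
hom_ref/het/hom_alt/missing; the alt allele is the panel-defined variant
allele and is never re-polarized by group frequency, so "MAF" throughout
means variant-allele frequency even where it would exceed 0.5. TaqMan-style
assays yield no phase, so any phase separators in VCF input are accepted
and discarded. All per-(group, locus) statistics run on integer genotype
counts with an explicit missing count, keeping typed and nominal
denominators distinct.

## Count reconstruction from rounded tables

Published tables print genotype proportions and MAFs to three decimals.
For n ≤ 200 the inverse problem is solved exactly: enumerate every typed
sample size n in a window (default nominal ± 5) and every integer triple
summing to n, and minimize lexicographically (max rounding discrepancy
over the three proportions and the MAF; then |n − nominal|; then n).
Rounding is half-away-from-zero, implemented in integer arithmetic so a
residual of exactly zero certifies that the counts reproduce every printed
digit. A uniqueness flag reports whether another triple attains the same
residual anywhere in the window (monomorphic rows, for instance, fit every
n exactly).

This surfaces a real feature of the source tables: the Paiter-Surui TPMT
rows are only consistent with 88 typed individuals and the Munduruku rows
with 91–92, against a nominal 90 — undisclosed dropout or overcount that a
naive frequency × 90 conversion would silently distort. Whether the true
denominators differ or the printed values contain typos cannot be decided
from the tables; the solver reports both the best fit and its uniqueness
rather than hiding the question.

## Statistics

**HWE.** Pearson χ² against (p², 2pq, q²)·n with df = 1 and no continuity
correction (what the source analysis used), plus the exact conditional
test: enumerate all heterozygote counts compatible with the observed
minor-allele count and sum the probabilities of configurations no more
probable than the observed one (no mid-p). Monomorphic loci return
χ² = 0, p = 1 by convention. Both p-values are always reported because
they genuinely disagree at rare alleles: the Paiter NUDT15 counts (79/9/2)
give χ² p = 0.016 but exact p = 0.055.

**Homogeneity and Cramér's V.** Pearson χ² on the r×c table with
(r−1)(c−1) df for the p-value; V = √(X²/(n·min(r−1, c−1))). Magnitude
labels use the conventional Cohen cut points (0.1/0.3/0.5); the source
called 0.33 "large", which these bands label "intermediate" — the bands
are a parameter and the numeric V is always printed. Zero marginals are a
caller error (drop the empty category), not silently repaired.

**FST.** From group alt-allele frequencies: HS = unweighted mean of
2p(1−p), HT = 2p̄(1−p̄) at the unweighted mean frequency (equal nominal
group sizes justify equal weights). Both HT−HS and the normalized
(HT−HS)/HT are computed; the normalized GST form is the headline because
it is what the published per-locus values (0.02, 0.11) actually are — the
raw differences (0.001, 0.015) match no printed value. HT = 0 (all groups
fixed the same way) returns FST = 0 flagged degenerate. No
Weir–Cockerham variance components: the target is the
heterozygosity-based statistic, not a sample-size-corrected estimator.

**Two-locus EM and LD.** Only the double heterozygote has latent phase;
its cis fraction is updated from the current haplotype frequencies and all
other classes contribute fixed haplotype counts. Initialization at linkage
equilibrium; convergence when every haplotype frequency moves < 1e-10 or
1000 iterations. The log-likelihood trace is retained and tests assert it
never decreases. D = p11 − pA·pB; D′ normalizes by the sign-appropriate
bound; R² = D²/(pA(1−pA)pB(1−pB)). Monomorphic loci are an error (LD
undefined), and individuals missing either genotype are excluded pairwise.
Tests validate EM against a brute-force likelihood oracle (the margins are
fixed by the data, leaving one free parameter, maximized by dense grid
plus bounded refinement) at tolerance 1e-6, and against closed-form LD of
the simulator's generating haplotype frequencies on a 50,000-per-group
draw. The published overall-cohort D′ = 0.96 / R² = 0.86 is *not* a
reproduction target: every count reconstruction consistent with the
printed tables yields D′ ≈ 0.97 and R² ≈ 0.92, so the published value must
reflect per-individual discordances visible only in the raw data.

## Star-allele calling

Calling is exhaustive consistency against a declarative YAML definition
table (TPMT *1, *2, *3A, *3B, *3C; NUDT15 *1, *3): a candidate diplotype
is any unordered haplotype pair whose summed per-locus alt counts equal
the observed genotype. On this panel the only ambiguous pattern is the
rs1800460/rs1142345 double heterozygote (*1/*3A vs *3B/*3C). The default
policy picks the pair with fewest variant haplotypes (*1/*3A), motivated
by the near-complete positive LD of the two sites; an `em_frequency`
policy (highest Hardy–Weinberg diplotype probability under supplied
haplotype frequencies) is available. The choice is not phenotype-neutral —
*1/*3A is IM, *3B/*3C is PM — and the miscall rate has the closed form
2·f(*3B)·f(*3C) / (2·f(*1)·f(*3A) + 2·f(*3B)·f(*3C)), asserted against
simulation; at the observed frequencies it is ~5×10⁻⁴. Any missing
genotype at a gene's loci yields a no-call (no imputation); no-calls are
counted and reported, never dropped silently.

## CPIC translation

Gene phenotype = count of no-function haplotypes (0 → NM, 1 → IM,
2 → PM), from the functionality column of the same YAML table. Compound
classes and dosing categories follow the guideline mapping exactly
(PM for both genes still maps to "reduce"; no stricter category exists).
Report percentages default to the nominal group size as denominator
(matching the published percentages over n = 90) with no-calls shown
alongside; a called-only denominator is available.

## Rebuilding individuals from marginal counts

The group × TPMT-phenotype homogeneity table requires per-individual
two-locus genotypes, but the published input is two marginal count
triples. These are joined by the comonotone coupling: sort variant
dosages at each locus and pair rank-by-rank, the unique joint distribution
with maximal positive dependence. This is exact when LD is complete and is
the assumption the published haplotype analysis itself makes; it yields
phenotype counts 89/1/0, 88/3/0, 57/28/3 and V = 0.33, robust (0.326–0.334)
across the admissible count reconstructions.

## The pinned cohort fixture

`data/joint_cohort_fixture.tsv` is a synthetic 270-individual
reconstruction built programmatically (`fixtures.build_joint_fixture`)
from the published per-individual statements: Yanomami 3 NUDT15
heterozygotes + 1 TPMT *1/*3A, disjoint; Munduruku 3 NUDT15 het + 1
NUDT15 hom + 3 *1/*3A, disjoint; Paiter-Surui 2 NUDT15 hom, 9 NUDT15 het
(4 co-occurring with *1/*3A — the compound IMs), 3 TPMT PMs (2 ×
*3A/*3A, 1 × *3A/*3C), 23 further TPMT IMs (21 × *1/*3A, 2 × *1/*3B),
remainder wild-type. It reproduces the dosing-category percentages
exactly (95.6/4.4/0.0, 92.2/6.7/1.1, 58.9/31.1/10.0) but cannot
simultaneously match every printed marginal (its Munduruku group holds 90
individuals where some printed rows imply 92 typed; its Paiter *3A
frequency is 0.167 vs the published 0.180): the per-individual truth is
under-determined by the printed tables, and the fixture pins the
quantities the dosing analysis needs. The published Munduruku percentages
92.4/6.5 are arithmetically impossible over n = 90 (and inconsistent with
the 5.6% quoted elsewhere in the source); the fixture's 92.2/6.7/1.1 are
the nearest integer-consistent values and the discrepancy is documented,
not fitted.

## Synthetic cohorts

The generator draws two TPMT star haplotypes i.i.d. from a group's
haplotype distribution and two NUDT15 alleles from its alt frequency
(random mating ⇒ HWE by construction), derives unphased genotypes through
the same definition table the caller uses, and applies
missing-completely-at-random dropout per locus. Defaults are the study
conditions: three groups of 90 at the published star-allele/NUDT15
frequencies, missingness 0. Haplotype-level simulation makes the TPMT-pair
LD an emergent property, so EM estimates can be checked against closed
forms. Randomness uses one global seed with CRC32-keyed child streams per
group and per (group, locus) missingness mask, so adding a group never
perturbs existing draws; identical config + seed is byte-identical output.
`drift_scenario` produces group frequencies hitting a target normalized
FST (symmetric spread around a base frequency, bisection on the spread,
within 5%). The generator does not model mutation, selection, admixture or
genotyping error, so passing tests demonstrate pipeline correctness under
clean HWE data, not robustness to assay artifacts.

## Problem sizes and numerical conventions

Exhaustive reconstruction searches n ≤ 200 (instances here are ~90);
property tests sweep all HWE configurations with n ≤ 30 and all 27 TPMT
genotype combinations; simulation checks use 90–50,000 individuals per
group, sized so sampling error is well inside the asserted 3-SE bands.
Display rounding is half-away-from-zero everywhere (3 decimals for
frequencies, 1 for percentages, 2 for V and FST); internal arithmetic is
unrounded. P-values print to 4 decimals, below 1e-4 as "<0.0001".

## Limitations

Only the four panel variants are considered: rare TPMT alleles (*4 and
beyond), CNVs and novel variants are out of scope, and *1 is assigned by
default exactly as in the source survey. The exact HWE test and EM phasing
assume a biallelic autosomal site in a homogeneous group. The inverse
count solver assumes the printed values were produced by rounding exact
proportions — a typo in the source propagates into the "best" counts,
mitigated only by the residual/uniqueness report.
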