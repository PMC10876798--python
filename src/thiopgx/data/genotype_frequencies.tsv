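# Published per-group genotype proportions and variant-allele frequencies
# (MAF) for the thiopurine panel in three Amazonian cohorts, nominal n = 90
# per group. Proportions are as printed: rounded to 3 decimals.
group	locus_id	f_hom_ref	f_het	f_hom_alt	maf
Yanomami	rs116855232	0.967	0.033	0.0	0.017
Munduruku	rs116855232	0.957	0.033	0.011	0.027
Paiter-Surui	rs116855232	0.878	0.100	0.022	0.072
Yanomami	rs1142345	0.989	0.011	0.0	0.006
Munduruku	rs1142345	0.967	0.033	0.0	0.016
Paiter-Surui	rs1142345	0.648	0.318	0.034	0.193
Yanomami	rs1800460	0.989	0.011	0.0	0.006
Munduruku	rs1800460	0.967	0.033	0.0	0.016
Paiter-Surui	rs1800460	0.648	0.330	0.023	0.188
Yanomami	rs1800462	1.0	0.0	0.0	0.0
Munduruku	rs1800462	1.0	0.0	0.0	0.0
Paiter-Surui	rs1800462	1.0	0.0	0.0	0.0
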