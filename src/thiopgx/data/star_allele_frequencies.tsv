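# Published per-group TPMT star-allele frequencies (3 decimals) for the
# three Amazonian cohorts; used for comparison, not as input to calling.
group	star	freq
Yanomami	*1	0.994
Yanomami	*3A	0.006
Yanomami	*3B	0.0
Yanomami	*3C	0.0
Munduruku	*1	0.984
Munduruku	*3A	0.016
Munduruku	*3B	0.0
Munduruku	*3C	0.0
Paiter-Surui	*1	0.803
Paiter-Surui	*3A	0.180
Paiter-Surui	*3B	0.011
Paiter-Surui	*3C	0.006
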