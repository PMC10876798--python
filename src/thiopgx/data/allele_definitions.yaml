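# Star-allele definition + functionality table for the thiopurine panel.
# Mirrors the CPIC TPMT/NUDT15 definition and allele-functionality tables
# restricted to the four assayed variants. Rows: star alleles; variants:
# panel sites carrying the alt allele on that haplotype.
TPMT:
  - star: "*1"
    variants: []
    function: normal
  - star: "*2"
    variants: [rs1800462]
    function: no_function
  - star: "*3A"
    variants: [rs1800460, rs1142345]
    function: no_function
  - star: "*3B"
    variants: [rs1800460]
    function: no_function
  - star: "*3C"
    variants: [rs1142345]
    function: no_function
NUDT15:
  - star: "*1"
    variants: []
    function: normal
  - star: "*3"
    variants: [rs116855232]
    function: no_function
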