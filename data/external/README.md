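Place user-supplied public sequence files here (see the top-level README,
section "External data"):

  AT4G30825.fasta      protein sequence of Arabidopsis AT4G30825 (904 aa)
  NC_000932_atpFA.gb   GenBank slice of NC_000932 with atpF and atpA genes
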