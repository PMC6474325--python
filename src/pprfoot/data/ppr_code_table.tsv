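# Default nucleotide-specificity table: (residue6, residue1prime) -> allowed
# nucleotides, primary preference first.  User-replaceable; unknown pairs
# resolve to the wildcard X.  A pair with residue6 = S and no entry is
# emitted as X flagged purine-preferring.
residue6	residue1prime	nucleotides
T	D	G
T	N	A
N	D	U
N	N	C,U
S	N	A
S	D	G
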