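# Transmembrane helix boundaries of the bovine rod opsin reference
# (residue = codon position, 1-based inclusive).
helix	start	end
TM1	34	64
TM2	71	100
TM3	106	140
TM4	150	172
TM5	200	229
TM6	241	276
TM7	285	309
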