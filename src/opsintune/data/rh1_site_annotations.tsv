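# Literature annotations for well-characterised RH1 tuning substitutions
# (bovine rod opsin numbering; bovine residue listed as ancestral).
# delta_nm values are registered defaults used only for the flagged
# best-effort estimate; direction is the robust part of the annotation.
site	ancestral	substituted	delta_nm	direction	label
83	D	N	-2	blue	D83N
90	G	S	-13	blue	G90S
96	Y	V	0	context	Y96V
122	E	Q	-15	blue	E122Q
124	A	S	-4	blue	A124S
164	A	S	2	red	A164S
207	M	L	0	context	M207L
211	H	C	-4	blue	H211C
253	M	T	-2	blue	M253T
261	F	Y	10	red	F261Y
265	W	Y	-15	blue	W265Y
269	A	T	14	red	A269T
292	A	S	-10	blue	A292S
295	A	S	-4	blue	A295S
300	S	A	2	red	S300A
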