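# Additive five-sites rule for LWS pigments (bovine rod opsin numbering).
# base_lambda_nm for the ancestral state S164/H181/Y261/T269/A292 is 560.
# delta_nm applies when the substituted residue replaces the ancestral one.
site	ancestral	substituted	delta_nm	citation
164	S	A	-7	five-sites rule, registered default
181	H	Y	-28	five-sites rule, registered default
261	Y	F	-8	five-sites rule, registered default
269	T	A	-15	five-sites rule, registered default
292	A	S	-27	five-sites rule, registered default
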