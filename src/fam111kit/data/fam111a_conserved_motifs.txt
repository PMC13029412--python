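# Seven conserved motifs of the FAM111A family, PROSITE-like syntax.
# name<TAB>pattern ; [AB] = two-way alternative, x = any residue.
M1	[AT]-[LV]-x-x-D-G-R-[FL]
M2	S-V-x-x-[IL]
M3	[LV]-[LF]-T-x-x-H-[VL]
M4	D-x-A-x-L-x-L
M5	I-I-G-H-P-x-[GE]-x-x-K
M6	G-x-S-G-S-P-V
M7	[LV]-x-x-x-H-x-x-G
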