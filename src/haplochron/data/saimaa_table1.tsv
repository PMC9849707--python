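haplotype	TG1	TG2	TG3	TG4	TG5
H1	3	12	48	28	40
H2	0	4	4	4	10
H3	10	14	21	19	63
H4	0	0	3	1	2
H5	1	0	2	1	0
H6	0	0	1	1	1
H7	0	0	0	1	7
H8	0	0	0	0	4
H9	3	1	0	0	0
H10	1	0	0	0	0
H11	1	0	0	0	0
H12	3	0	0	0	0
H13	1	1	2	1	1
H14	0	1	0	0	0
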