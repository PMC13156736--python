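# SYNTHETIC placeholder RNase H1 position-weight table (seeded pseudorandom weights).
# It stands in for a cleavage-preference table derived from experimental data, which
# users supply via the rnaseh1_table config key. Lower score = higher predicted cleavage.
position	A	C	G	T
0	0.92	0.41	0.68	0.20
1	0.28	0.96	0.33	0.72
2	0.47	0.94	0.48	0.09
3	0.49	0.56	0.41	0.06
4	0.71	0.46	0.54	0.01
5	0.34	0.84	0.29	0.23
6	0.50	0.42	0.91	0.72
7	0.78	0.93	0.00	0.59
8	0.70	0.01	0.89	0.69
9	0.86	0.85	0.60	0.46
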