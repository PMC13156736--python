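# DNA nearest-neighbor free-energy parameters, dG at 37 C (kcal/mol), 0.1 kcal/mol resolution.
# kind: stack (key = 5'->3' top-strand dinucleotide of a Watson-Crick helix step)
#       hairpin|bulge|internal (key = loop size in nt; sizes past 10 log-extrapolated)
kind	key	energy
stack	AA	-1.0
stack	AC	-1.4
stack	AG	-1.3
stack	AT	-0.9
stack	CA	-1.5
stack	CC	-1.8
stack	CG	-2.2
stack	CT	-1.3
stack	GA	-1.3
stack	GC	-2.2
stack	GG	-1.8
stack	GT	-1.4
stack	TA	-0.6
stack	TC	-1.3
stack	TG	-1.5
stack	TT	-1.0
hairpin	3	3.5
hairpin	4	3.5
hairpin	5	3.3
hairpin	6	4.0
hairpin	7	4.2
hairpin	8	4.3
hairpin	9	4.5
hairpin	10	4.6
hairpin	11	4.7
hairpin	12	4.9
hairpin	13	5.0
hairpin	14	5.1
hairpin	15	5.2
hairpin	16	5.3
hairpin	17	5.4
hairpin	18	5.5
hairpin	19	5.6
hairpin	20	5.6
hairpin	21	5.7
hairpin	22	5.8
hairpin	23	5.9
hairpin	24	5.9
hairpin	25	6.0
hairpin	26	6.0
hairpin	27	6.1
hairpin	28	6.1
hairpin	29	6.2
hairpin	30	6.3
bulge	1	4.0
bulge	2	2.9
bulge	3	3.1
bulge	4	3.2
bulge	5	3.3
bulge	6	3.5
bulge	7	3.7
bulge	8	3.9
bulge	9	4.1
bulge	10	4.3
bulge	11	4.4
bulge	12	4.6
bulge	13	4.7
bulge	14	4.8
bulge	15	4.9
bulge	16	5.0
bulge	17	5.1
bulge	18	5.2
bulge	19	5.3
bulge	20	5.3
bulge	21	5.4
bulge	22	5.5
bulge	23	5.6
bulge	24	5.6
bulge	25	5.7
bulge	26	5.7
bulge	27	5.8
bulge	28	5.8
bulge	29	5.9
bulge	30	6.0
internal	2	3.2
internal	3	3.6
internal	4	4.0
internal	5	4.4
internal	6	4.6
internal	7	4.8
internal	8	4.9
internal	9	4.9
internal	10	5.0
internal	11	5.1
internal	12	5.3
internal	13	5.4
internal	14	5.5
internal	15	5.6
internal	16	5.7
internal	17	5.8
internal	18	5.9
internal	19	6.0
internal	20	6.0
internal	21	6.1
internal	22	6.2
internal	23	6.3
internal	24	6.3
internal	25	6.4
internal	26	6.4
internal	27	6.5
internal	28	6.5
internal	29	6.6
internal	30	6.7
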