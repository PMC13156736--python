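# Uniform null RNase H1 position-weight table: every base at every gap position
# weighs 0.25, so all candidates score 0.25 regardless of sequence.
position	A	C	G	T
0	0.25	0.25	0.25	0.25
1	0.25	0.25	0.25	0.25
2	0.25	0.25	0.25	0.25
3	0.25	0.25	0.25	0.25
4	0.25	0.25	0.25	0.25
5	0.25	0.25	0.25	0.25
6	0.25	0.25	0.25	0.25
7	0.25	0.25	0.25	0.25
8	0.25	0.25	0.25	0.25
9	0.25	0.25	0.25	0.25
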