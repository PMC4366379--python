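positions	change	accessions	exclusive
70	T>A	L100	0
130	M>L	VIR320	0
135	S>N	JI1794,L100,VIR320	0
159	M>T	JI1794	0
179	A>T	JI1794,L100,VIR320	0
211	M>I	JI1794	0
211	M>T	L100,VIR320	1
252	H>Y	L100,VIR320	1
254	V>I	L100,VIR320	1
279	M>I	L100,VIR320	1
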