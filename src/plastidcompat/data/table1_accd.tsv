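positions	change	accessions	exclusive
1-11	absence of MINEDPSSLTD (11 AA)	721,L100,VIR320	0
46	D>H	JI1794,721,L100,VIR320	0
47	K>T	L100,VIR320	1
48	I>L	721	0
109	R>S	721,L100,VIR320	0
112	I>R	JI1794	0
116	R>T	721	0
130-135	del ISDTND (6 AA)	721,L100	0
141-143	ins DTN (3 AA)	JI1794	0
175-180	ins ISDTND (6 AA)	721,L100,VIR320	0
196-203	del TNIKDICE (8 AA)	L100,VIR320	1
210	P>R	721,L100,VIR320	0
214	del E	L100,VIR320	1
224-225	SD>IH	L100,VIR320	1
240	E>R	L100,VIR320	1
249	Q>P	JI1794,L100,VIR320	0
309-339	del 31 AA	721,L100,VIR320	0
340-342	del EEE (3 AA)	L100,VIR320	1
345	Q>P	721	0
375-376	HP>NR	721,L100,VIR320	0
379	E>Q	L100,VIR320	1
383	N>K	L100,VIR320	1
384	Q>K	721,L100,VIR320	0
399	ins E	721,L100	0
399	ins Q	VIR320	0
400-401	ins EE (2 AA)	721	0
407	Q>P	721	0
559	E>Q	L100,VIR320	1
603-610	addition of SNWTENEN (8 AA)	JI1794	0
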