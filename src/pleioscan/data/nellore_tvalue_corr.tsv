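trait	BW	WG	PG	CW	PW	MW	CY	PY	MY
BW	1.000	0.202	0.062	0.321	-0.063	-0.045	0.272	-0.078	-0.070
WG	0.202	1.000	0.490	0.790	0.473	0.483	0.751	0.410	0.406
PG	0.062	0.490	1.000	0.360	0.238	0.184	0.604	0.441	0.425
CW	0.321	0.800	0.360	1.000	0.325	0.359	0.877	0.265	0.274
PW	-0.063	0.473	0.238	0.325	1.000	0.886	0.308	0.890	0.802
MW	-0.044	0.483	0.185	0.359	0.886	1.000	0.303	0.770	0.855
CY	0.272	0.751	0.604	0.877	0.308	0.303	1.000	0.384	0.383
PY	-0.078	0.410	0.441	0.265	0.890	0.770	0.384	1.000	0.887
MY	-0.070	0.407	0.425	0.274	0.802	0.853	0.383	0.887	1.000
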