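trait	BW	WG	PG	CW	PW	MW	CY	PY	MY
BW	1.000	0.140	0.079	0.277	-0.059	-0.056	0.217	-0.051	-0.052
WG	0.140	1.000	0.501	0.776	0.493	0.507	0.734	0.435	0.430
PG	0.079	0.501	1.000	0.351	0.291	0.234	0.571	0.456	0.429
CW	0.277	0.776	0.351	1.000	0.381	0.412	0.884	0.329	0.335
PW	-0.059	0.493	0.291	0.381	1.000	0.884	0.393	0.917	0.833
MW	-0.056	0.507	0.234	0.412	0.884	1.000	0.382	0.798	0.888
CY	0.217	0.734	0.571	0.884	0.393	0.382	1.000	0.451	0.445
PY	-0.051	0.435	0.456	0.329	0.917	0.798	0.451	1.000	0.885
MY	-0.052	0.430	0.429	0.335	0.833	0.888	0.445	0.885	1.000
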