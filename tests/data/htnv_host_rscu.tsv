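amino_acid	codon	overall	sk	rus	ch	hs	apo	nc
F	UUU	1.33	1.33	1.34	1.32	0.99	0.90	0.86
F	UUC	0.67	0.67	0.66	0.68	1.01	1.10	1.14
L	UUA	1.85	1.87	1.76	1.81	0.54	0.26	0.14
L	UUG	0.97	0.96	1.07	0.95	0.83	0.69	0.59
L	CUU	1.01	0.99	1.19	1.02	0.87	0.58	0.41
L	CUC	0.46	0.45	0.43	0.52	1.09	1.53	1.60
L	CUA	0.96	0.97	0.86	0.96	0.46	0.57	0.53
L	CUG	0.75	0.76	0.70	0.74	2.21	2.39	2.73
I	AUU	1.37	1.37	1.39	1.37	1.15	0.69	0.76
I	AUC	0.58	0.59	0.51	0.59	1.29	1.87	1.87
I	AUA	1.05	1.05	1.11	1.04	0.56	0.43	0.37
V	GUU	1.37	1.35	1.33	1.48	0.80	0.35	0.26
V	GUC	0.65	0.63	0.67	0.68	0.92	0.99	0.81
V	GUA	1.21	1.27	1.21	0.99	0.53	0.45	0.40
V	GUG	0.77	0.75	0.80	0.85	1.75	2.21	2.52
S	UCU	1.29	1.29	1.27	1.29	1.18	1.39	1.06
S	UCC	0.52	0.54	0.56	0.46	1.20	1.45	1.80
S	UCA	2.03	2.00	2.04	2.13	0.99	0.62	0.65
S	UCG	0.12	0.12	0.12	0.13	0.28	0.40	0.34
S	AGU	1.17	1.17	1.36	1.12	0.98	0.65	0.97
S	AGC	0.87	0.88	0.65	0.87	1.37	1.49	1.18
P	CCU	1.66	1.64	1.63	1.74	1.22	1.29	1.54
P	CCC	0.38	0.36	0.48	0.44	1.20	1.58	1.42
P	CCA	1.76	1.81	1.63	1.60	1.19	0.82	0.92
P	CCG	0.20	0.19	0.26	0.22	0.39	0.30	0.12
T	ACU	0.85	0.80	1.00	1.06	1.06	0.83	0.56
T	ACC	0.35	0.34	0.34	0.37	1.31	1.50	1.93
T	ACA	2.72	2.78	2.61	2.50	1.22	1.07	0.97
T	ACG	0.08	0.08	0.05	0.07	0.41	0.60	0.54
A	GCU	1.20	1.22	1.25	1.12	1.12	1.15	1.17
A	GCC	0.57	0.56	0.39	0.63	1.52	1.85	1.98
A	GCA	2.17	2.16	2.29	2.19	1.01	0.84	0.73
A	GCG	0.06	0.06	0.07	0.06	0.35	0.16	0.12
Y	UAU	1.40	1.38	1.42	1.46	0.95	0.72	0.85
Y	UAC	0.60	0.62	0.58	0.54	1.05	1.28	1.15
H	CAU	1.31	1.28	1.33	1.44	0.90	0.56	0.70
H	CAC	0.69	0.72	0.67	0.56	1.10	1.44	1.30
Q	CAA	1.08	1.11	1.11	0.96	0.57	0.42	0.38
Q	CAG	0.92	0.89	0.89	1.04	1.43	1.58	1.62
N	AAU	1.45	1.47	1.46	1.39	1.01	0.71	0.75
N	AAC	0.55	0.53	0.54	0.61	0.99	1.29	1.25
K	AAA	1.03	1.03	1.00	1.04	0.93	0.67	0.55
K	AAG	0.97	0.97	1.00	0.96	1.07	1.33	1.45
D	GAU	1.44	1.46	1.38	1.41	1.00	0.73	0.58
D	GAC	0.56	0.54	0.62	0.59	1.00	1.27	1.42
E	GAA	1.12	1.09	1.15	1.25	0.92	0.74	0.84
E	GAG	0.88	0.91	0.85	0.75	1.08	1.26	1.16
C	UGU	1.38	1.37	1.54	1.39	0.98	1.42	1.21
C	UGC	0.62	0.63	0.46	0.61	1.02	0.58	0.79
R	CGU	0.51	0.53	0.51	0.41	0.49	0.58	0.48
R	CGC	0.22	0.19	0.25	0.33	0.94	0.80	0.52
R	CGA	0.53	0.57	0.35	0.40	0.69	0.71	0.94
R	CGG	0.41	0.37	0.60	0.47	1.14	1.22	0.92
R	AGA	2.35	2.36	2.45	2.26	1.44	1.27	1.50
R	AGG	1.99	1.97	1.84	2.12	1.31	1.42	1.65
G	GGU	1.23	1.23	1.30	1.20	0.69	0.54	0.79
G	GGC	0.43	0.42	0.42	0.46	1.25	1.54	1.46
G	GGA	1.26	1.28	1.24	1.19	1.09	0.87	0.75
G	GGG	1.09	1.07	1.04	1.15	0.97	1.06	1.00
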