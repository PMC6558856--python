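AA	H11	H12	H2	NCI	P11	P12	P2	SASA	V	F	A1	E	T	A2
A	0.62	2.1	-0.5	0.007	8.1	0	0.046	1.181	27.5	-1.27	0.49	15	-0.8	1.064
C	0.29	1.4	-1.0	-0.037	5.5	1.48	0.128	1.461	44.6	-1.09	0.26	5	0.83	1.412
D	-0.9	10.0	3.0	-0.024	13.0	40.7	0.105	1.587	40.0	1.42	0.78	50	1.65	0.866
E	-0.74	7.8	3.0	0.007	12.3	49.91	0.151	1.862	62.0	1.6	0.84	55	-0.92	0.851
F	1.19	-9.2	-2.5	0.038	5.2	0.35	0.29	2.228	115.5	-2.14	0.42	10	0.18	1.091
G	0.48	5.7	0.0	0.179	9.0	0	0	0.881	0	1.86	0.48	10	-0.55	0.874
H	-0.4	2.1	-0.5	-0.011	10.4	3.53	0.23	2.025	79.0	-0.82	0.84	56	0.11	1.105
I	1.38	-8.0	-1.8	0.022	5.2	0.15	0.186	1.81	93.5	-2.89	0.34	13	-1.53	1.152
K	-1.5	5.7	3.0	0.018	11.3	49.5	0.219	2.258	100	2.88	0.97	85	-1.06	0.93
L	1.06	-9.2	-1.8	0.052	4.9	0.45	0.186	1.931	93.5	-2.29	0.4	16	-1.01	1.25
M	0.64	-4.2	-1.3	0.003	5.7	1.43	0.221	2.034	94.1	-1.84	0.48	20	-1.48	0.826
N	-0.78	7.0	2.0	0.005	11.6	3.38	0.134	1.655	58.7	1.77	0.81	49	3.0	0.776
P	0.12	2.1	0.0	0.240	8.0	0	0.131	1.468	41.9	0.52	0.49	15	-0.8	1.064
Q	-0.85	6.0	0.2	0.049	10.5	3.53	0.18	1.932	80.7	1.18	0.84	56	0.11	1.015
R	-2.53	4.2	3.0	0.044	10.5	52.0	0.291	2.56	105	2.79	0.95	67	-1.15	0.873
S	-0.18	6.5	0.3	0.005	9.2	1.67	0.062	1.298	29.3	3.0	0.65	32	1.34	1.012
T	-0.05	5.2	-0.4	0.003	8.6	1.66	0.108	1.525	51.3	1.18	0.7	32	0.27	0.909
V	1.08	-3.7	-1.5	0.057	5.9	0.13	0.14	1.645	71.5	-1.75	0.36	14	-0.83	1.383
W	0.81	-10	-3.4	0.038	5.4	2.1	0.409	2.663	145.5	-3.78	0.51	17	-0.97	0.893
Y	0.26	-1.9	-2.3	0.024	6.2	1.61	0.298	2.368	117.3	-3.3	0.76	41	-0.29	1.161
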