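patient	esr	hscrp	osteocalcin	vas	wbc	neutrophil
S1	2	0.17	1.54	2	6.34	3.98
S2	7	0.12	2.55	2	9.46	5.63
S3	16	0.12	3.5	5	9.75	5.49
S4	20	2.73	2.96	7	6.62	3.89
S5	21	7.2	5.43	8	7.04	5.01
S6	24	7.84	6.39	3	4.43	1.41
S7	14	4.01	3.06	8	2.67	1.15
S8	29	7.21	2.37	9	10.61	6.42
S9	72	26.15	1.88	9	6.52	4.25
S10	9	2.52	7.05	1	8.15	4.65
S11	20	1.14	4.95	4	4.80	2.46
S12	40	7.84	0.29	6	5.42	3.42
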