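# Calibration pairs for the purifying-selection-corrected whole-mitogenome clock:
# published (divergence, age) estimates for mtDNA haplogroup R0a'b subclades.
# divergence: mutations over the whole molecule (ML or rho column of the source table)
# age_ka: the corresponding corrected-clock age, in ka
# Rows for R0a'b, R0a, R0a1a, R0a2 and R0a2b1a are deliberately withheld and
# serve as held-out validation points.
clade	divergence	age_ka
R0a1	9.54	26.39
R0a1	8.00	21.89
R0a1a1	3.89	10.31
R0a1a1	2.67	7.00
R0a1a1a	1.35	3.51
R0a1a1a	1.22	3.16
R0a1a1a1	0.63	1.63
R0a1a1a1	0.40	1.03
R0a1a2	1.79	4.65
R0a1a2	2.33	6.09
R0a1a3	4.41	11.73
R0a1a3	6.25	16.88
R0a1a3a	2.16	5.64
R0a1a3a	2.67	7.00
R0a1a4	2.85	7.49
R0a1a4	3.33	8.78
R0a1a5	3.49	9.21
R0a1a5	2.75	7.22
R0a1b	0.69	1.78
R0a1b	0.67	1.73
R0a2'3	7.66	20.92
R0a2'3	6.06	16.34
R0a2a	3.34	8.82
R0a2a	2.29	5.99
R0a2a1	0.98	2.53
R0a2a1	0.67	1.73
R0a2b	4.75	12.69
R0a2b	4.29	11.41
R0a2b1	4.01	10.62
R0a2b1	4.21	11.19
R0a2b1b	3.05	8.04
R0a2b1b	3.20	8.43
R0a2b1b1	1.76	4.57
R0a2b1b1	1.75	4.55
R0a2b2	1.50	3.89
R0a2b2	1.11	2.87
R0a2c	4.64	12.37
R0a2c	3.50	9.25
R0a2c1	0.84	2.16
R0a2c1	0.67	1.73
R0a2d	4.67	12.45
R0a2d	4.43	11.79
R0a2f	5.56	14.94
R0a2f	6.27	16.93
R0a2f1	2.07	5.41
R0a2f1	2.22	5.80
R0a2f1a	1.07	2.76
R0a2f1a	1.17	3.03
R0a2f1b	1.27	3.29
R0a2f1b	1.33	3.45
R0a2g	4.15	11.02
R0a2g	3.29	8.68
R0a2g1	3.14	8.27
R0a2g1	3.00	7.89
R0a2g1a	2.48	6.49
R0a2g1a	2.67	7.00
R0a2h	3.49	9.21
R0a2h	2.67	7.00
R0a2i	1.64	4.27
R0a2i	1.67	4.34
R0a2j	5.16	13.81
R0a2j	6.67	18.07
R0a2k	5.50	14.78
R0a2k	7.00	19.01
R0a2m	0.55	1.41
R0a2m	0.50	1.29
R0a2n	4.93	13.17
R0a2n	3.86	10.23
R0a2n1	2.45	6.41
R0a2n1	1.75	4.55
R0a2n2	2.45	6.41
R0a2n2	2.33	6.09
R0a2o	3.83	10.15
R0a2o	2.40	6.28
R0a2o1	1.67	4.35
R0a2o1	1.25	3.24
R0a2q	1.47	3.82
R0a2q	1.00	2.59
R0a2r	4.64	12.37
R0a2r	3.82	10.12
R0a3	5.19	13.89
R0a3	3.80	10.06
R0a3a	4.24	11.26
R0a3a	3.67	9.71
R0a4	0.46	1.19
R0a4	0.33	0.85
R0a5	6.92	18.77
R0a5	5.50	14.77
R0a6	1.15	2.98
R0a6	1.00	2.59
R0b	5.71	15.34
R0b	5.00	13.37
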