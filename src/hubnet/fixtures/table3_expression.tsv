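gene	percentile_a	p_a	fc_a	percentile_b	p_b	fc_b
APC	7	1.99E-06	-4.782	21	3.15E-08	-1.272
APP	2	4.68E-09	-19.629	1	9.83E-64	-3.799
AXIN1	27	5.00E-03	-1.766	41	3.70E-02	-1.607
CCND1	27	6.00E-03	-2.555	39	1.90E-02	-1.08
CDC42	3	8.32E-08	-2.631	15	2.44E-12	-1.249
CDH1	18	3.16E-04	-2.573	6	1.31E-28	-2.816
CREBBP	1	1.95E-09	-3.821	12	1.66E-16	-1.408
CTNNA1	22	1.00E-03	-3.401	1	4.41E-60	-3.627
EP300	14	5.14E-05	-1.732	34	2.00E-03	-1.147
KAT2B	2	2.52E-08	-3.205	7	4.59E-25	-2.279
NFKB1	10	3.40E-07	-29.14	5	1.09E-19	-1.8
NOTCH2	11	1.93E-05	-5.629	18	4.85E-10	-1.189
PSEN1	2	8.94E-09	-2.626	14	5.38E-14	-1.338
RAC1	42	1.28E-01	-1.223	10	3.25E-18	-1.438
SMAD3	2	6.69E-09	-10.45	27	3.03E-05	-1.191
VEGFA	33	2.60E-02	-6.262	1	1.25E-52	-3.364
AKT1	16	9.24E-05	2.159	26	3.30E-06	1.224
CDH2	30	6.00E-03	3.89	4	5.73E-32	2.648
EGFR	34	1.40E-02	3.384	39	5.00E-03	1.083
GSK3B	31	7.00E-03	1.398	13	1.63E-14	1.364
HDAC1	5	2.38E-07	2.406	6	1.26E-24	1.542
JUN	26	2.00E-03	3.799	20	1.12E-09	1.957
LEF1	5	3.97E-07	13.361	1	8.79E-50	3.083
NOTCH1	15	6.77E-05	2.394	1	5.05E-45	2.461
NOTCH3	20	4.16E-04	11.153	2	2.37E-38	3.021
SMAD2	8	2.25E-06	1.791	9	1.41E-20	1.358
SMAD4	2	2.50E-02	1.276	37	4.57E-42	2.024
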