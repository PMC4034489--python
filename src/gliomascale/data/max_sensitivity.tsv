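# Published maximal absolute sensitivity coefficients m_e per parameter
# (maximum of |S_e| over all 20 factors and 4 initial glucose levels) with
# the glucose level (g/L) attaining each maximum. Reference transcription
# for plot comparison only; full-scale sweep values are stochastic and are
# never used as a numerical test oracle.
param	m_time	glucose_time	m_total	glucose_total	m_mig	glucose_mig	m_prolif	glucose_prolif
k1	5.98	0.3	11.91	0.3	12.28	0.3	11.13	0.3
k1_i	6.60	0.3	14.88	0.3	17.38	0.3	13.06	0.3
k2	13.20	0.3	21.69	0.3	22.99	0.3	20.78	0.3
k3	11.75	0.3	21.53	0.3	22.49	0.3	21.61	0.3
k4	17.94	0.3	38.42	0.3	43.66	0.3	34.89	0.3
k5	6.80	0.3	13.55	0.3	16.12	0.3	11.37	0.3
k6	6.80	0.3	9.88	0.3	10.55	0.3	9.56	0.3
k7	11.18	0.3	15.95	1.125	17.10	1.125	15.08	1.125
k8	5.57	0.3	13.63	2.25	15.01	2.25	12.92	2.25
k9	11.14	0.3	11.14	2.25	12.16	2.25	10.59	2.25
k10	8.25	0.3	13.76	0.3	14.77	0.3	13.16	0.3
k11_m1	5.58	1.125	12.54	1.125	13.45	1.125	11.71	1.125
k11_c1	3.71	0.3	11.33	2.25	11.95	2.25	10.95	2.25
k11_m2	7.73	0.3	14.87	0.3	16.39	0.3	14.91	0.3
k11_c2	12.43	0.3	14.21	0.3	16.55	0.3	12.31	0.3
k12_i	8.66	0.3	18.44	0.3	20.67	0.3	16.93	0.3
k12	8.25	0.3	15.22	0.3	17.52	0.3	13.79	0.3
k13_m1	10.93	0.3	21.62	0.3	23.88	0.3	19.88	0.3
k13_c1	5.36	0.3	10.57	0.3	10.65	0.3	10.56	0.3
k13_m2	11.96	0.3	19.50	0.3	19.63	0.3	19.31	0.3
k13_c2	7.01	1.125	15.41	0.3	15.51	0.3	15.46	0.3
k14	8.66	0.3	18.14	0.3	21.16	0.3	14.95	0.3
k15_i	6.49	1.125	12.11	1.125	10.14	1.125	14.23	1.125
k15	14.85	0.3	32.23	0.3	36.54	0.3	29.02	0.3
k16	9.04	0.3	15.40	0.3	17.48	0.3	13.18	0.3
k17_m1	7.01	0.3	13.86	0.3	15.18	0.3	12.85	0.3
k17_c1	6.19	0.3	12.30	1.125	13.24	1.125	10.97	1.125
k17_m2	3.92	0.3	8.52	0.3	9.44	0.3	8.54	1.125
k17_c2	9.95	0.3	20.23	1.125	22.69	1.125	18.10	1.125
k18_m	9.90	0.3	11.81	0.3	11.73	0.3	11.71	0.3
k18_c	6.80	0.3	14.18	0.3	15.80	0.3	12.30	0.3
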