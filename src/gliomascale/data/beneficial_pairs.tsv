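# Published combined scalings (param1*factor1 with param2*factor2) that
# slowed expansion (dM_time > 0.01) while shrinking the tumour
# (dM_total < -0.01) at the stated initial glucose level (g/L).
param1	factor1	glucose	param2	factor2
k1	0.01	4.5	k7	100
k1	10	2.25	k11_c2	5
k1	50	1.125	k10	0.01
k1	50	2.25	k9	100
k1	50	2.25	k11_c2	10
k1	50	4.5	k1_i	0.01
k1	50	4.5	k9	50
k1	50	4.5	k9	100
k1	50	4.5	k10	0.01
k1_i	0.01	2.25	k8	50
k1_i	0.01	4.5	k8	50
k2	0.01	4.5	k4	0.01
k2	0.01	4.5	k7	0.01
k2	50	1.125	k1_i	0.01
k2	50	1.125	k9	100
k2	50	1.125	k10	0.01
k2	50	2.25	k1_i	0.01
k2	50	2.25	k9	100
k2	50	2.25	k10	0.01
k2	50	4.5	k9	100
k2	50	4.5	k10	0.01
k2	50	4.5	k11_c2	10
k4	50	1.125	k2	100
k4	50	1.125	k3	0.01
k4	50	1.125	k10	100
k4	50	2.25	k9	0.01
k4	50	4.5	k8	100
k7	50	4.5	k8	100
k7	50	4.5	k9	0.01
k11_c2	5	1.125	k8	10
k11_c2	5	1.125	k9	0.1
k11_c2	5	1.125	k10	10
k11_c2	5	1.125	k12	5
k11_c2	5	2.25	k3	0.01
k11_c2	5	2.25	k4	0.1
k11_c2	5	2.25	k7	0.1
k11_c2	5	2.25	k10	50
k11_c2	5	4.5	k8	10
k11_c2	5	4.5	k9	0.1
k11_c2	10	1.125	k12	10
k11_c2	50	1.125	k8	100
k11_c2	50	1.125	k9	0.01
k11_c2	50	2.25	k8	100
k11_c2	50	2.25	k12	50
k11_c2	50	4.5	k8	100
k11_c2	50	4.5	k9	0.01
k11_c2	50	4.5	k10	100
k11_c2	50	4.5	k12	50
k11_c2	100	2.25	k12	100
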