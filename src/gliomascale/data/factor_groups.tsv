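# Published Factor+/Factor- selection of the one-at-a-time sweep:
# Factor+ scalings pushed dM_time above 9 at 0.3 g/L glucose; Factor-
# scalings pushed dM_total below -0.8 at 4.5 g/L. Empty field = no entry.
param	factor_plus	factor_minus
k1	10;50;100	0.01
k1_i		0.01
k2	10;50;100	0.01
k3	0.01;0.1	50;100
k4	0.01;0.1	50;100
k7	0.01;0.1	50;100
k8	10;50;100
k9	0.01;0.1	50;100
k10	10;50;100	0.01
k11_c1		10;50;100
k11_m2	50;100
k11_c2	0.01;0.1	5;10;50;100
k12_i		0.01;0.1
k12	5;10;50;100	0.01;0.1
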