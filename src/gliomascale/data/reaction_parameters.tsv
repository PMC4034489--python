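# Published baseline reaction constants of the miR-451/AMPK/mTORC1 glioblastoma
# network model, plus the glucose-consumption triple (r, C1, C2).
# perturbable = 1 marks the 31 constants varied in the sensitivity sweep.
name	value	unit	perturbable
k1	1.2e-9	pmol^-1 L s^-1	1
k1_i	1	pmol L^-1	1
k2	3e-2	pmol^-1 L s^-1	1
k3	3e1	s^-1	1
k4	1.4583e-2	s^-1	1
k5	3.6e2	s^-1	1
k6	1.0467e-2	s^-1	1
k7	5.626e-3	s^-1	1
k8	6.4167e-3	s^-1	1
k9	6e-2	pmol^-1 L s^-1	1
k10	3.6e2	s^-1	1
k11_m1	5e2	pmol L^-1	1
k11_c1	1.8e5	pmol L^-1 s^-1	1
k11_m2	5e2	pmol L^-1	1
k11_c2	1.8e6	pmol L s^-1	1
k12_i	6e-1	DC	1
k12	6e2	s^-1	1
k13_m1	1e2	pmol L^-1	1
k13_c1	6e2	pmol L^-1 s^-1	1
k13_m2	1e2	pmol L^-1	1
k13_c2	6e4	pmol L^-1 s^-1	1
k14	3.6e2	s^-1	1
k15_i	5	pmol L^-1	1
k15	3.6e2	s^-1	1
k16	3.6e2	s^-1	1
k17_m1	1e2	pmol L^-1	1
k17_c1	3.6e3	pmol L^-1 s^-1	1
k17_m2	1e2	pmol L^-1	1
k17_c2	3.6e5	pmol L^-1 s^-1	1
k18_m	1.5104e3	pmol L^-1	1
k18_c	4.86e3	pmol L^-1 s^-1	1
r	1.17e-2	mmol L^-1 s^-1	0
C1	8.571e-1	DC	0
C2	1.429e-1	DC	0
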