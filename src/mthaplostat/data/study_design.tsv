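haplotype	LV_F	LV_M	LV_U	CO_F	CO_M	CO_U	ZA_F	ZA_M	ZA_U	KF_F	KF_M	KF_U	SI_F	SI_M	SI_U
H1	0	0	0	0	0	0	0	0	0	0	1	0	0	0	0
H9	0	1	0	0	0	0	0	0	0	18	41	0	0	1	0
H11	6	13	0	3	5	0	1	0	0	0	1	0	0	0	0
Z1	7	32	1	0	6	0	1	0	0	0	4	0	0	0	0
Z2	0	0	0	0	0	0	0	1	0	0	0	0	0	0	0
Z3	0	0	0	0	0	0	0	0	0	5	10	0	0	0	0
Z4	0	0	0	0	0	0	0	0	0	0	2	0	0	0	0
Z5	0	0	0	0	0	0	0	0	0	4	1	0	0	0	0
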