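peptidase_id	species	accession	family_printed	tetrad	hh	homolog_mark	rpkm	rescue	rpkm_uncertain	key_residues	key_residues_uncertain	is_pseudogene	curator_flag
TmL13	Tm	KP303287	L	QCHN	0	0	19726.5	8496.6	0	GGWMALA	0	0
TmL5	Tm	KP303279	L	QCHN	0	0	1356.6	572.7	0	GGWMAFV	0	0
TmL11	Tm	KP303285	L	QCHN	0	0	1149.4	354.9	0	GGEDGLT	0	0
TmL2	Tm	KP303276	L	QCHN	0	0	337.3	263.5	0	GGLMALE	0	0
TmL4	Tm	KP303278	L	QCHN	0	0	326.9	168.9	0	GGWMAFK	0	0
TmL1	Tm	KP303275	L	QCHN	0	0	162.2	113.9	0	GGYMALQ	0	0
TmL30	Tm	KP303289	L-homolog	ESHN	0	1	130.3	104.4	0	GGSIALD	0	0	shared-accession
TmL29	Tm	KP303289	L-homolog	QAHN	0	1	130.3	104.4	0	GGLTALS	0	0	shared-accession
TmL3	Tm	KP303277	L	QCHN	0	0	62.1	31.3	0	GGLMALE	0	0
TmL9	Tm	KP303283	L	QCHN	0	0	72.0	46.0	0	LEMEIYY	0	0
TmL7	Tm	KP303281	L	QCHN	0	0	25.3	11.7	0	MQLDTFI	0	0
TmL6	Tm	KP303280	L	QCHN	0	0	15.8	5.8	0	GGWMAFK	0	0
TmL8	Tm	KP303282	L	QCHN	0	0	5.7	3.7	0	MQLDTFR	0	0
TmL15	Tm	KP303288	L	QCHN	0	0	0.2	0.2	0	GGWMAFQ	0	0
TmB33	Tm	KP303302	B	QCSN	1	0	2489.6	1160.4	0	GGWPDGD	0	0	tetrad-print-discrepancy
TmB20	Tm	KP303293	B-like	QCHN	0	0	448.4	221.5	0	GGYMNGY	0	0
TmB25	Tm	KP303297	B-like	QCHN	0	0	672.6	296.7	0	GGWPSGN	0	0
TmB26	Tm	KP303298	B-like	QCHN	0	0	657.5	431.6	0	GGSSSGN	0	0
TmB18	Tm	KP303291	B	QCHN	1	0	283.2	175.8	0	GGYPSGD	0	0
TmB17	Tm	KP303290	B	QCHN	1	0	163.9	99.0	0	GGFPAGE	0	0
TmB32	Tm	KP303301	B-homolog	QSHN	0	1	77.9	37.5	0	GGYLTGF	0	0
TmB23	Tm	KP303295	B-like	QCHN	0	0	48.8	29.3	0	GGYVTGY	0	0
TmB19	Tm	KP303292	B-like	QCHN	0	0	34.2	24.9	0	GGYIGGY	0	0
TmB27	Tm	KP303299	B-like	QCHN	0	0	26.5	13.9	0	GGWMAFQ	0	0
TmB24	Tm	KP303296	B-like	QCHN	0	0	20.0	6.5	0	GGAPNGN	0	0
TmB28	Tm	KP303300	B-like	QCHN	0	0	4.0	2.2	0	SGSSISH	0	0	table4-asterisk
TmB22	Tm	KP303294	B-like	QCHN	0	0	1.2	0.7	0	GGYMGGN	0	0
TmO12	Tm	KP303286	O	QCHN	0	0	38.4	22.2	0	GGDVALE	0	0
TmF10	Tm	KP303284	F	QCHN	0	0	23.4	8.4	0	GGLMALP	0	0
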