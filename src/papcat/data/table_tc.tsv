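peptidase_id	species	accession	gene_id	chromosome	family_printed	tetrad	hh	homolog_mark	rpkm	rescue	rpkm_uncertain	key_residues	key_residues_uncertain	is_pseudogene	curator_flag
NP_001164001	Tc	NP_001164001	LOC659441	10	L	QCHN	0	0	77228.2		1	GGWMALA	0	0
NP_001164314	Tc	NP_001164314	LOC659502	10	L	QCHN	0	0	25848.8		1	GGWMALA	0	0
XP_970644	Tc	XP_970644	LOC659226	10	L	QCHN	0	0	42.7		1	GGLMALQ	0	0
XP_970773	Tc	XP_970773	LOC659367	10	L-homolog	ESHN	0	1	35.0		1	GGHATLS	0	0
XP_970951	Tc	XP_970951	LOC659565	10	L	QCHN	0	0	0.28		1	AGLMAVQ	0	0
XP_971698	Tc	XP_971698	LOC660368	7	L	QCHN	0	0	2387.6		1	GGWMAFK	0	0
XP_971867	Tc	XP_971867	LOC660551	7	L	QCHN	0	0	71.99		1	GGWMAFK	0	0
XP_971752	Tc	XP_971752	LOC660428	7	L	QCHN	0	0	70.98		1	GGYLSKR	0	0
XP_971975	Tc	XP_971975	LOC660669	7	L	QCHN	0	0	70.02		1	GGWMALH	0	0
NC_007422	Tc	NC_007422	LOC660491	7	pseudogene	-	0	0			1	-	1	1	pseudogene
XP_974298	Tc	XP_974298	LOC663145	3	B	QCHN	1	0	3142.15		1	GGWPDGD	0	0
NP_001164205	Tc	NP_001164205	LOC663117	3	B	QCHN	1	0	1132.96		1	GGMPSGG	0	0
XP_974244	Tc	XP_974244	LOC663090	3	B	QCHN	1	0	248.71		1	GGYMSGN	0	0
XP_974220	Tc	XP_974220	LOC663066	3	B-like	QCHN	0	0	79.91		1	GGFPAGS	0	0
XP_966750	Tc	XP_966750	LOC655148	8	B-like	QCHN	0	0	443.27		1	GGAPHGY	0	0
XP_966663	Tc	XP_966663	LOC655077	8	B-like	QCHN	0	0	1.18		1	GGYSSGN	0	0
XP_968689	Tc	XP_968689	LOC657117	8	B-homolog	QSTN	0	1	57.6		1	SGYTAGS	0	0
XP_968767	Tc	XP_968767	LOC657203	8	B-like	QCHN	0	0	82.17		1	GGYSGGS	0	0
XP_008196467	Tc	XP_008196467	LOC656957	8	B-like	QCHN	0	0			1	GGYOYGE	1	0	tcas4-change
XP_008196465	Tc	XP_008196465	LOC657038	8	B-like	QCHN	0	0			1	GGYTTXE	1	0	tcas4-change
NP_001164088	Tc	NP_001164088	LOC663234	7	L	QCHN	0	0	1309.16		1	GGEDALT	0	0
XP_969833	Tc	XP_969833	LOC658343	3	L	QCHN	0	0	0.02		1	GGWIALH	0	0
XP_967834	Tc	XP_967834	LOC656198	7	B-homolog	QSHN	0	1	28.64		1	GGYLTGF	0	0
XP_970512	Tc	XP_970512	LOC659087	4	O	QCHN	0	0	11.99		1	GGDIALE	0	0
XP_973607	Tc	XP_973607	LOC662417	7	F	QCHN	0	0	2.32		1	GGLMALP	0	0
XP_001814509	Tc	XP_001814509	LOC100141668	1	K	QCHN	0	0	0		1	GGSLSVY	0	0
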