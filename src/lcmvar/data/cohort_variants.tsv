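sample_label	gene	transcript	hgvs_p	hgvs_c	gnomad_af
EEP001ECT	KCNH5	NM_139318.4	p.Gly808Val	c.2423G>T	0
EEP001ECT	MITF	NM_198159.2	p.Ser258Leu	c.773C>T	0.0000119
EEP001ECT EEP001EU	HERC2	NM_004667.5	p.Val3327Met	c.9979G>A	0.0345
EEP002ECT	KRAS	NM_033360.3	p.Gly12Asp	c.35G>A	0.00000401
EEP005ECT	ZNF804B	NM_181646.2	p.Glu1340Gln	c.4018G>C	0
EEP005ECT	CSMD3	NM_198123.1	p.Thr1246Met	c.3737C>T	0.0000639
EEP005ECT	CSMD3	NM_198123.1		c.8440+4C>T	0
EEP005ECT	NSD1	NM_022455.4	p.His918Tyr	c.2752C>T	0
EEP005ECT	NCOA1	NM_003743.4	p.Ala1081Val	c.3242C>T	0
EEP005ECT	MUC16	NM_024690.2	p.Gly8417Val	c.25250G>T	0
EEP005ECT	SMOX	NM_001270691.1	p.Ala356Thr	c.1066G>A	0
EEP005ECT	EWSR1	NM_013986.3	p.Gln146*	c.436C>T	0
EEP005ECT	NTRK2	NM_006180.4	p.Glu634Asp	c.1902G>C	0
EEP005ECT	PRDM9	NM_020227.2	p.Pro663Ser	c.1987C>T	0
EEP005EU	CASP8	NM_001080125.1	p.Glu71Gly	c.212A>G	0
EEP005EU	PSIP1	NM_001128217.1	p.Leu368Arg	c.1103T>G	0
EEP005EU	DNAH7	NM_018897.2	p.Gly91Val	c.272G>T	0
EEP005EU	FANCD2	NM_033084.3	p.Lys871Asn	c.2613A>C	0.000204
EEP005ECT EEP005EU	JAK2	NM_004972.3	p.Pro500_Pro501fs	c.1498_1499insC	0
EEP006ECT	ATRX	NM_000489.4	p.Gln1551*	c.4651C>T	0
EEP006ECT	KTN1	NM_001079521.1	p.Pro992_Pro993fs	c.2974_2975insC	0
EEP006ECT	CNOT1	NM_016284.4	p.Pro1254Ser	c.3760C>T	0.00000399
EEP006ECT	CHD2	NM_001271.3		c.-228T>C	0
EEP008ECT	BRIP1	NM_032043.2	p.Arg579His	c.1736G>A	0.0000278
EEP008EU	AR	NM_000044.3	p.Glu710Lys	c.2128G>A	0
EEP008EU	DMD	NM_004006.2	p.Gly3235Asp	c.9704G>A	0
EEP008EU	EPCAM	NM_002354.2	p.Gly79Trp	c.235G>T	0
EEP008EU	SMC3	NM_005445.3	p.Gly531Cys	c.1591G>T	0
EEP008EU	SYNE2	NM_182914.2	p.Leu6190Ile	c.18568C>A	0
EEP009ECT	TP53	NM_000546.5	p.Glu271Lys	c.811G>A	0
EEP009EU	COL1A1	NM_000088.3	p.Gly209Asp	c.626G>A	0
EEP009EU	DSCAM	NM_001389.3	p.Val1261Leu	c.3781G>C	0.0000201
EEP010ECT	PKD1L1	NM_138295.3	p.Gln122_Leu125del	c.363_374delACAGGCGCCTCT	0
EEP010ECT	ABL2	NM_007314.3	p.Ala114Glu	c.341C>A	0
EEP010EU	ETV5	NM_004454.2	p.Tyr429_Tyr430fs	c.1286_1287insA	0
EEP010EU	KDM6A	NM_021140.3		c.619+1_619+2delAAGT	0
EEP012ECT	RYR1	NM_000540.2	p.Thr1406Met	c.4217C>T	0.0000442
EEP012EU	AURKAIP1	NM_001127230.1	p.Ser72Arg	c.216C>A	0
EEP012EU	OBSCN	NM_001271223.2	p.Ala809Val	c.2426C>T	0.0000487
EEP012EU	HIP1	NM_005338.6		c.2466-4G>A	0
EEP014EU	FBN1	NM_000138.4		c.5788+7G>T	0
EEP014EU	SORCS1	NM_001013031.2	p.Val722Ala	c.2165T>C	0
EEP015ECT	ERBB3	NM_001982.3	p.Gly325Arg	c.973G>A	0
EEP015EU	LAMA2	NM_000426.3	p.Arg2604*	c.7810C>T	0.00000797
EEP015EU	MYO3A	NM_017433.4	p.Thr1501Lys	c.4502C>A	0
EEP015EU	RNASEL	NM_021133.3	p.Ala99Thr	c.295G>A	0
EEP015EU	RYR1	NM_000540.2	p.Gln240His	c.720G>T	0
EEP015EU	DNAH7	NM_018897.2	p.Ala1578Asp	c.4733C>A	0
EEP015EU	CTNNA1	NM_001903.3		c.1063-10834C>A	0
EEP015EU	PTCH1	NM_000264.3	p.Ser764Gly	c.2290A>G	0
EEP015EU	FAT3	NM_001008781.2	p.Ser2776Asn	c.8327G>A	0
EEP015EU	ATRX	NM_000489.4	p.Val194Ala	c.581T>C	0
EEP015EU	KLHL6	NM_130446.2	p.Arg308His	c.923G>A	0.000299
EEP015ECT EEP015EU	DYSF	NM_003494.3	p.Arg1041Cys	c.3121C>T	0.000168
EEP015ECT EEP015EU	TROAP	NM_005480.3	p.Ala235Asp	c.704C>A	0.0000398
EEP016ECT	MTUS2	NM_001033602.2	p.Arg468Gln	c.1403G>A	0.00075
EEP016EU	PIK3C2B	NM_002646.3	p.Val685Ile	c.2053G>A	0.0000837
EEP016EU	PTK2	NM_005607.4	p.Pro857Leu	c.2570C>T	0
EEP017EU	USP24	NM_015306.2	p.Ala909Val	c.2726C>T	0
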