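# Synthetic amplicon-deep-sequencing read counts for the verification study.
# Counts are constructed to reproduce the reported per-variant replicate
# outcomes (which samples detected each variant); the depths and alt-read
# numbers themselves are invented at the reported >2000x coverage scale.
patient_id	gene	sample_id	depth	alt_reads
EEP009	TP53	EEP009_ECT_WGA1	2612	118
EEP009	TP53	EEP009_ECT_WGA2	2540	97
EEP002	KRAS	EEP002_ECT_WGA1	2480	55
EEP002	KRAS	EEP002_ECT_WGA2	2510	1
EEP001	HERC2	EEP001_ECT_WGA1	2705	0
EEP001	HERC2	EEP001_ECT_WGA2	2633	1
EEP001	HERC2	EEP001_EU_WGA1	2590	0
EEP001	HERC2	EEP001_EU_WGA2	2481	0
EEP005	JAK2	EEP005_ECT_WGA1	2388	0
EEP005	JAK2	EEP005_ECT_WGA2	2460	0
EEP005	JAK2	EEP005_EU_WGA1	2521	1
EEP005	JAK2	EEP005_EU_WGA2	2404	0
EEP015	TROAP	EEP015_ECT_WGA1	2599	0
EEP015	TROAP	EEP015_ECT_WGA2	2685	0
EEP015	TROAP	EEP015_EU_WGA1	2550	1
EEP015	TROAP	EEP015_EU_WGA2	2470	0
EEP015	DYSF	EEP015_EU_WGA1	2450	41
EEP015	DYSF	EEP015_EU_WGA2	2390	0
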