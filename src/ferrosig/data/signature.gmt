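FR20_UP_SUPPRESSORS	ferroptosis suppressors up-regulated in BBDI-resistant cells	FTH1	GPX4	G6PD	AKR1C2	AKR1C3	ALDH3A2	NQO1	FTL
FR20_DOWN_DRIVERS	ferroptosis drivers down-regulated in BBDI-resistant cells	ACSL4	ATF4	ATG3	BID	HIF1A	HMGB1	HMOX1	LIFR	MTDH	PGRMC1	SNCA	VDAC2
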