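gene	role
FTH1	suppressor
GPX4	suppressor
G6PD	suppressor
AKR1C2	suppressor
AKR1C3	suppressor
ALDH3A2	suppressor
NQO1	suppressor
FTL	suppressor
ACSL4	driver
ATF4	driver
ATG3	driver
BID	driver
HIF1A	driver
HMGB1	driver
HMOX1	driver
LIFR	driver
MTDH	driver
PGRMC1	driver
SNCA	driver
VDAC2	driver
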