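#priors	low_risk=0.45	high_risk=0.55
gene	probe_id	class	mean	sd
LMF1	46142_at	low_risk	101.6708	31.6461
LMF1	46142_at	high_risk	88.6869	29.5986
DLC1	210762_s_at	low_risk	868.5886	578.3862
DLC1	210762_s_at	high_risk	648.4284	530.6969
PKLR	222078_at	low_risk	14.3474	6.872
PKLR	222078_at	high_risk	11.002	5.5501
ATP6V0D1	212041_at	low_risk	1388.054	398.6874
ATP6V0D1	212041_at	high_risk	1209.6369	325.7233
CCDC99	221685_s_at	low_risk	277.1923	56.2284
CCDC99	221685_s_at	high_risk	300.0086	60.678
SCLY	219808_at	low_risk	58.3824	13.2988
SCLY	219808_at	high_risk	63.6222	13.7703
PDPK1	204524_at	low_risk	297.6373	117.3514
PDPK1	204524_at	high_risk	253.7384	103.0455
FAM164A	205308_at	low_risk	264.8707	106.5128
FAM164A	205308_at	high_risk	223.8295	96.6066
SMPD1	209420_s_at	low_risk	278.5686	84.5316
SMPD1	209420_s_at	high_risk	239.3571	65.4393
XPO1	208775_at	low_risk	1674.3741	344.9824
XPO1	208775_at	high_risk	1824.6274	400.4278
ZAK	218833_at	low_risk	132.694	67.7063
ZAK	218833_at	high_risk	159.0546	79.1456
STK24	208855_s_at	low_risk	2248.6647	529.6098
STK24	208855_s_at	high_risk	2457.9982	576.496
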