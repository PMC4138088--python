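locus	dialect	cp_score	mt_score	sec_score	suba	suba_method	c2010	targetp_cp
At3g08530	consensus	0.0	0.0	2.7	yes	MS/MS	yes
At2g40060	consensus	0.0	0.0	2.0	yes	MS/MS	yes
At1g07890	consensus	0.8	9.0	0.0	no		yes
At1g77490	consensus	22.8	5.0	4.9	yes	MS/MS	yes
At2g04270	consensus	11.2	4.3	0.4	yes	MS/MS	yes
At4g08390	consensus	17.0	5.3	2.2	yes	MS/MS,GFP	yes
At4g35000	consensus	0.0	5.8	0.0	yes	MS/MS	yes
At1g29900	consensus	20.1	3.9	0.0	yes	MS/MS	yes
At1g32470	consensus	8.4	16.2	2.3	yes	MS/MS	yes
At1g36180	consensus	17.7	6.9	0.2	no		no
At5g35360	consensus	20.8	0.0	0.0	yes	MS/MS	yes
At5g46420	consensus	14.4	2.7	3.1	yes	MS/MS	yes
At1g18080	consensus	0.0	0.0	0.0	yes	MS/MS	no
At2g33340	consensus	0.0	0.0	0.0	yes	MS/MS	yes
At4g22910	consensus	11.6	0.0	0.0	no		yes
At5g13840	consensus	18.1	0.0	0.0	no		yes
At1g24130	consensus	10.8	0.0	0.5	no		yes
At4g02660	consensus	0.0	0.0	0.0	yes	MS/MS	no
At5g58230	consensus	0.4	0.0	0.0	yes	MS/MS	yes
At1g15850	consensus	9.2	0.0	2.9	no		yes
At1g08520	consensus	22.8	0.4	0.0	yes	MS/MS	yes
At1g67120	consensus	0.0	1.1	3.2	yes	MS/MS	yes
At4g34450	consensus	0.4	0.0	4.0	no		no
At1g51350	consensus	20.4	0.0	3.9	no		yes
At5g57460	consensus	6.6	3.0	4.4	yes	MS/MS	yes
At1g09180	consensus	0.4	0.0	19.9	yes	MS/MS	yes
At1g05810	consensus	19.2	1.2	2.8	no		yes
At4g35860	consensus	0.0	0.0	5.9	yes	MS/MS	yes
At5g57960	consensus	17.3	1.4	0.0	yes	MS/MS	yes
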