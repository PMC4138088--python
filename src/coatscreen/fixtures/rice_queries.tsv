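protein_id	organism	system	complex	subunit	domains
CHC1_yeast	yeast	CCV	triskelion	heavy chain	PF01394;PF09268;PF13838;PF00637;PS50236
APL4_yeast	yeast	CCV	AP1	γ	PS00435
AP1B1_human	human	CCV	AP1	β1	PF01602
APL1_yeast	yeast	CCV	AP2	β2	PS00867
APB1/2_arabidopsis	arabidopsis	CCV	AP2	β2	PF01602
AP2M1_rice_ref	human	CCV	AP2	μ2	PF00928
AP3D1_human	human	CCV	AP3	δ	PF01602
AP3B1_human	human	CCV	AP3	β3	PF01602
AP3M1_arabidopsis	arabidopsis	CCV	AP3	μ3	PF00928
AP4B1_human	human	CCV	AP4	β4	PF01602;PF09066
AP4E1_human	human	CCV	AP4	ε	PF01602
AP5M1_human	human	CCV	AP5	μ5	PF00928
COPA_human	human	COPI	B-COPI	α	PS50082;PS50294;PS00678
COPB2_arabidopsis	arabidopsis	COPI	B-COPI	β′	PS50294;PS50082
COPE_human	human	COPI	B-COPI	ε	PF04733
COPD_human	human	COPI	F-COPI	δ	PF00928
COPZ_yeast	yeast	COPI	F-COPI	ζ	PS50234
ARFA_arabidopsis	arabidopsis	GTPase	ArfA	Arf	PF00025
ARFB_arabidopsis	arabidopsis	GTPase	ArfB	Arf	PF00025
ARFD_arabidopsis	arabidopsis	GTPase	ArfD	Arf	PF00025
ARFB2_arabidopsis	arabidopsis	GTPase	ArfB2	Arf	PF00025
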