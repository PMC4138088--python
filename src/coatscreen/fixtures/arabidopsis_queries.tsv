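protein_id	organism	system	complex	subunit	domains
CHC1_yeast	yeast	CCV	triskelion	heavy chain	PF01394;PF09268;PF13838;PF00637;PS50236
CLC1_yeast	yeast	CCV	triskelion	light chain	PF01086
CLC1_arabidopsis	arabidopsis	CCV	triskelion	light chain	PF01086
APL4_yeast	yeast	CCV	AP1	γ	PS00435
AP1B1_human	human	CCV	AP1	β1	PF01602
APL1_yeast	yeast	CCV	AP2	β2	PS00867
APB1/2_arabidopsis	arabidopsis	CCV	AP2	β2	PF01602
AP2M1_human	human	CCV	AP2	μ2	PS51072
AP3D1_human	human	CCV	AP3	δ	PF01602
AP3B1_human	human	CCV	AP3	β3	PF01602
AP4E1_human	human	CCV	AP4	ε	PF01602
AP4M1_human	human	CCV	AP4	μ4	PS51072
AP4S1_human	human	CCV	AP4	σ4	PS51072
AP5M1_human	human	CCV	AP5	μ5	PS51072
COPA_human	human	COPI	B-COPI	α	PS50082;PS50294;PS00678
COPB2_arabidopsis	arabidopsis	COPI	B-COPI	β′	PS50294;PS50082
COPB2_human	human	COPI	B-COPI	β′	PS50294;PS50082
COPE_human	human	COPI	B-COPI	ε	PF04733
COPG_arabidopsis	arabidopsis	COPI	F-COPI	γ	PF01602;PF08752
COPD_human	human	COPI	F-COPI	δ	PS51072
COPZ_yeast	yeast	COPI	F-COPI	ζ	PS50234
ARFA_arabidopsis	arabidopsis	GTPase	ArfA	Arf	PS51417;PF00025
ARFB_arabidopsis	arabidopsis	GTPase	ArfB	Arf	PS51417;PF00025
ARFD_arabidopsis	arabidopsis	GTPase	ArfD	Arf	PS51417;PF00025
ARFB2_arabidopsis	arabidopsis	GTPase	ArfB2	Arf	PS51417;PF00025
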