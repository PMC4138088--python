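locus	name	domains	role_text
LOC_Os11g01380	Clathrin heavy chain 1	PF01394;PF09268;PF13838;PF00637;PS50236;PS00878
LOC_Os12g01390	Clathrin heavy chain 2	PF01394;PF09268;PF13838;PF00637;PS50236;PS00878
LOC_Os04g35520	Probable L-ascorbate peroxidase 7 (APX7)	PS00435
LOC_Os02g34810	Probable L-ascorbate peroxidase 8 (APX8)	PS00435
LOC_Os11g41990	Armadillo/beta-catenin-like repeat family protein	PF01602
LOC_Os01g43630	Adaptin, putative	PF01602;PF09066
LOC_Os01g32880	AP-3 complex subunit delta	PF01602
LOC_Os01g38970	Carbamoyl-phosphate synthase large chain (CARB)	PS00867
LOC_Os05g22940	Acetyl-CoA carboxylase 2 (ACC2)	PS00867
LOC_Os12g34370	Adaptor complexes medium subunit family protein	PF00928
LOC_Os03g46650	Guanine nucleotide-binding protein subunit beta	PS50082;PS50294;PS00678
LOC_Os12g01922	Regulatory-associated protein of TOR 1 (RAPTOR1)	PS50082;PS50294
LOC_Os07g14530	PPR repeat containing protein	PF04733
LOC_Os03g59640	Magnesium-chelatase subunit ChlD	PS50234
LOC_Os03g59590	Mitochondrial Rho GTPase	PF00025
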