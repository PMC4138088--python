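locus	name	domains	role_text
At3g08530	AtCHC2	PF01394;PF09268;PF13838;PF00637;PS50236	Protein binding, vesicle transport, endocytosis
At2g40060	AtCLC1	PF01086	Vesicle transport
At1g07890	Putative ascorbate peroxidase	PS00435	Golgi organization, glycolysis, hyperosmotic response, photorespiration, protein folding (is a ascorbate peroxidase)
At1g77490	AttAPX	PS00435	Chloroplast-nucleus signalling, thylakoid membrane organization (is a ascorbate peroxidase)
At2g04270	AtRNEE/G	PS00435	Chloroplast mRNA processing, chloroplast organisation, thylakoid membrane organization (is a ribonuclease)
At4g08390	AtsAPX	PS00435	Oxidation-reduction processes (is a ascorbate peroxidase)
At4g35000	AtAPX3	PS00435	Oxidation-reduction processes (is a ascorbate peroxidase)
At1g29900	AtCarB	PS00867	Response to phosphate starvation, chromatin silencing, gluconeogenesis, metabolic processes
At1g32470	Putative H-protein of glycine decarboxylase	PS00867	Glycine processes, PSII assembly, rRNA processing, biosynthesis of cysteine
At1g36180	AtACC2	PS00867	Fatty acid and metabolic processes (is a acetyl CoA carboxylase)
At5g35360	AtCAC2	PS00867	Fatty acid and metabolic processes, brassinosteroid and polysaccharide biosynthesis (is a acetyl CoA carboxylase)
At5g46420	Putative RimM-like protein involved in 16S rRNA processing	PS00867	Virus defence, metabolic processes, gene silencing, ribosome biogenesis
At1g18080	AtRACK1A	PS50294;PS50082	Response to ABA, GA signalling, glycolysis, translation, salt stress, ribosome biogenesis, seed germination
At2g33340	AtPUB60	PS50294;PS50082	Nucleotide binding
At4g22910	AtFZR2 (AtCCS52A1)	PS50294;PS50082	Protein binding, cell growth, proteasome assembly, regulation of cell division
At5g13840	AtFZR3 (AtCCS52B)	PS50294;PS50082	Protein binding, DNA methylation, gamete generation, microtubule organization, proteasome assembly, cell division
At1g24130	Unknown protein	PS50294;PS50082	Nucleotide binding
At4g02660	Unknown protein	PS50294;PS50082	Signal transduction
At5g58230	AtMSI1	PS50294;PS50082	Protein binding, cell proliferation, chromatin modification, seed development, DNA replication
At1g15850	Unknown protein	PS50294;PS50082	Nucleotide binding
At1g08520	AtCHLD	PS50234;PF13519;PF01078	Chlorophyll biosynthesis, cytokinin metabolic process, photosynthesis
At1g67120	Unknown protein	PS50234;PF13519;PF01078	Cytoskeleton organization, embryo sac development, gluconeogenesis
At4g34450	Putative gamma subunit of coatomer adaptor complex	PF01602;PF08752	Cytoskeleton organization, protein transport, catabolic processes, vesicle transport
At1g51350	Unknown protein	PF01602	Unknown
At5g57460	Unknown protein	PS51072	Unknown
At1g09180	AtSARA1A	PS51417;PF00025	Intracellullar transport
At1g05810	AtRabA5e	PS51417;PF00025	Protein transport, GTP mediated signalling
At4g35860	AtRabB1c	PS51417;PF00025	Protein transport, vesicle transport, protein targeting to the vacuole
At5g57960	Putative GTPase of unknown function	PS51417;PF00025	GTP binding
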