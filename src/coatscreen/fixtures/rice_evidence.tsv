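locus	dialect	cp_score	mt_score	sec_score	suba	suba_method	c2010	targetp_cp
LOC_Os11g01380	single_predictor				no		no	true
LOC_Os12g01390	single_predictor				no		no	true
LOC_Os04g35520	single_predictor				no		no	true
LOC_Os02g34810	single_predictor				no		no	true
LOC_Os11g41990	single_predictor				no		no	true
LOC_Os01g43630	single_predictor				no		no	true
LOC_Os01g32880	single_predictor				no		no	true
LOC_Os01g38970	single_predictor				no		no	true
LOC_Os05g22940	single_predictor				no		no	true
LOC_Os12g34370	single_predictor				no		no	true
LOC_Os03g46650	single_predictor				no		no	true
LOC_Os12g01922	single_predictor				no		no	true
LOC_Os07g14530	single_predictor				no		no	true
LOC_Os03g59640	single_predictor				no		no	true
LOC_Os03g59590	single_predictor				no		no	true
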