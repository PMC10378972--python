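site_class	focal_change	cg_focal	cg_other	noncg_focal	noncg_other
FFD	G>A	5606	12488	11685	32153
FFD	C>T	6002	13654	11600	32310
NC	G>A	874	2466	4994	17494
NC	C>T	857	2427	5012	17482
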