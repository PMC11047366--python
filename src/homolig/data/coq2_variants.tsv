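# Missense variants of human COQ2 associated with primary CoQ deficiency, their location in
# the protein and pathogenicity classifications from four sources.
variant	position	wt_aa	mut_aa	location	sift	clinvar	lovd	franklin
p.Ser96Asn	96	S	N	Transmembrane helix S1	Pathogenic	Pathogenic	Not classified	Likely pathogenic
p.Arg123His	123	R	H	Transmembrane helix S2	Pathogenic	Uncertain significance	Not classified	Uncertain significance
p.Met132Arg	132	M	R	Loop between S2 and S3 (matrix side)	Pathogenic	Not provided	Affects function	Likely pathogenic
p.Arg147His	147	R	H	Loop between S2 and S3 (matrix side)	Pathogenic	Pathogenic/Likely pathogenic	Probably affects function	Pathogenic
p.Asn178Ser	178	N	S	Loop between S3 and S4 (intermembrane space side)	Tolerated	Conflicting classifications of pathogenicity	Probably affects function/Affects function	Likely pathogenic
p.Cys228Arg	228	C	R	Loop between S5 and S6 (intermembrane space side)	Pathogenic	Not reported	Not reported	Uncertain significance
p.Leu236Phe	236	L	F	Transmembrane helix S6	Pathogenic	Uncertain significance	Not reported	Uncertain significance
p.Thr244Ile	244	T	I	Transmembrane helix S6	Tolerated	Uncertain significance	Not classified	Uncertain significance
p.Tyr247Cys	247	Y	C	Loop between S6 and S7 (matrix side)	Pathogenic	Likely pathogenic	Affects function	Likely pathogenic
p.Ala252Val	252	A	V	Loop between S6 and S7 (matrix side)	Pathogenic	Not provided	Effect unknown	Uncertain significance
p.Thr275Ala	275	T	A	Loop between S6 and S7 (matrix side)	Tolerated	Not reported	Not reported	Uncertain significance
p.Gly340Ala	340	G	A	Transmembrane helix S9	Pathogenic	Uncertain significance	Not reported	Uncertain significance
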