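# Global RMSD (Angstrom) of each predicted COQ2 variant model against the wild-type model,
# ordered from most to least similar, with the SIFT pathogenicity call.
variant	sift	rmsd
p.Ser96Asn	Pathogenic	0.183
p.Met132Arg	Pathogenic	0.199
p.Leu236Phe	Pathogenic	0.207
p.Arg147His	Pathogenic	0.210
p.Asn178Ser	Tolerated	0.225
p.Gly340Ala	Pathogenic	0.237
p.Tyr247Cys	Pathogenic	0.246
p.Cys228Arg	Pathogenic	0.247
p.Thr244Ile	Tolerated	0.247
p.Arg123His	Pathogenic	0.256
p.Thr275Ala	Tolerated	0.257
p.Ala252Val	Pathogenic	0.268
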