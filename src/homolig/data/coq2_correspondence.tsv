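# Residue correspondence between the ApUbiA template (PDB 4OD5 chain A numbering) and human
# COQ2, for residues proposed to contact the substrates: the diphosphate (PPi) group and its
# two Mg2+ cofactor ions, the C1 atom of the isoprenoid tail, and the PHB carboxyl group.
homolog_residue	query_residue	role
D54	D134	PPi/Mg
D58	D138	PPi/Mg
R63	R143	PPi/Mg
R67	R147	PPi/Mg
Y115	Y195	PPi/Mg
K119	K199	PPi/Mg
D182	D255	PPi/Mg
D186	D259	PPi/Mg
N50	N130	tail-C1
D175	D248	tail-C1
Y178	Y251	tail-C1
R43	R123	PHB-carboxyl
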