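# Ligand components observed in the selected COQ2 homolog structures, plus the two query
# substrates (PHB and the undecaprenyl-phosphate stand-in 5TR for decaprenyl diphosphate).
# SMILES were reconstructed from the chemical identity of each component (names below); they
# are synthetic stand-ins for the wwPDB Chemical Component Dictionary descriptors and may
# differ from the deposited descriptors in stereochemistry or acyl-chain detail, which the
# 166-key structural fingerprints do not resolve. AJP reconstruction matches digitonin's
# molecular formula C56H92O29 exactly.
ccd_id	name	source_structure	smiles
PHB	p-hydroxybenzoic acid	4OD5_A	Oc1ccc(cc1)C(O)=O
GST	geranyl S-thiolodiphosphate	4OD5_A	CC(C)=CCC/C(C)=C/CSP(O)(=O)OP(O)(O)=O
MG	magnesium ion	4OD5_A	[Mg+2]
MPG	[(Z)-octadec-9-enyl] (2R)-2,3-bis(oxidanyl)propanoate	6M31_B	CCCCCCCC/C=C\CCCCCCCCOC(=O)[C@@H](O)CO
LDA	lauryl dimethylamine-N-oxide	6M31_B	CCCCCCCCCCCC[N+](C)(C)[O-]
PO4	phosphate ion	6M31_B	[O-]P([O-])([O-])=O
Y01	cholesterol hemisuccinate	8DJM_B	CC(C)CCC[C@@H](C)[C@H]1CC[C@H]2[C@@H]3CC=C4C[C@@H](CC[C@]4(C)[C@H]3CC[C@]12C)OC(=O)CCC(O)=O
AJP	digitonin	8DJM_B	CC1CCC2(OC1)OC1CC3C4CCC5CC(OC6OC(CO)C(OC7OC(CO)C(O)C(OC8OCC(O)C(O)C8O)C7O)C(O)C6OC6OC(CO)C(O)C(O)C6OC6OC(CO)C(O)C(O)C6O)C(O)CC5(C)C4CC(O)C3(C)C1C2C
GPP	geranyl diphosphate	4TQ3_B	CC(C)=CCC/C(C)=C/COP(O)(=O)OP(O)(O)=O
7PH	phosphatidic acid	7Q21_f	CCCCCCCCCCCCCCCC(=O)OC[C@H](COP(O)(O)=O)OC(=O)CCCCCCCCCCCCCCC
CDL	cardiolipin	7Q21_f	CCCCCCCC/C=C\CCCCCCCC(=O)OC[C@H](OC(=O)CCCCCCC/C=C\CCCCCCCC)COP(O)(=O)OC[C@@H](O)COP(O)(=O)OC[C@H](OC(=O)CCCCCCC/C=C\CCCCCCCC)COC(=O)CCCCCCC/C=C\CCCCCCCC
TRD	tridecane	7Q21_f	CCCCCCCCCCCCC
5TR	undecaprenyl phosphate	query	CC(C)=CCC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/CC/C(C)=C/COP(O)(O)=O
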