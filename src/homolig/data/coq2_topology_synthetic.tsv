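# Synthetic reconstruction of the human COQ2 membrane topology (nine transmembrane helices
# S1..S9 with alternating matrix / intermembrane-space loops; N-terminus matrix side,
# C-terminus intermembrane side). Exact helix boundaries are not published as numbers; these
# intervals are chosen to be consistent with every published variant location label and with
# the placement of the conserved motifs on the matrix loops S2-S3, S4-S5 and S6-S7.
# side: matrix | intermembrane | membrane
label	start	end	side	kind
N-terminus	1	88	matrix	terminus
S1	89	109	membrane	helix
S1-S2	110	115	intermembrane	loop
S2	116	131	membrane	helix
S2-S3	132	152	matrix	loop
S3	153	172	membrane	helix
S3-S4	173	182	intermembrane	loop
S4	183	193	membrane	helix
S4-S5	194	203	matrix	loop
S5	204	223	membrane	helix
S5-S6	224	231	intermembrane	loop
S6	232	245	membrane	helix
S6-S7	246	278	matrix	loop
S7	279	298	membrane	helix
S7-S8	299	305	intermembrane	loop
S8	306	325	membrane	helix
S8-S9	326	331	matrix	loop
S9	332	352	membrane	helix
C-terminus	353	371	intermembrane	terminus
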