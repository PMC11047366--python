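# Expected pairwise Tanimoto coefficients for the toy ligand catalog, computed with an
# independent structural-key implementation (Open Babel 3.1.1, MACCS fingerprint); the
# intersection/union key counts give the exact fraction. Diagonal entries are 1 by identity
# (except the empty-vs-empty convention, which no toy molecule triggers).
a	b	intersection	union	tanimoto
METH	ETOH	1	9	0.111111
METH	BENZ	0	4	0.000000
METH	PHEN	0	11	0.000000
METH	ACET	1	7	0.142857
METH	HEXA	1	10	0.100000
METH	IPRO	1	7	0.142857
METH	MGI	0	4	0.000000
ETOH	BENZ	0	12	0.000000
ETOH	PHEN	3	16	0.187500
ETOH	ACET	4	12	0.333333
ETOH	HEXA	3	16	0.187500
ETOH	IPRO	4	12	0.333333
ETOH	MGI	0	12	0.000000
BENZ	PHEN	3	10	0.300000
BENZ	ACET	0	10	0.000000
BENZ	HEXA	0	13	0.000000
BENZ	IPRO	0	10	0.000000
BENZ	MGI	0	6	0.000000
PHEN	ACET	3	14	0.214286
PHEN	HEXA	0	20	0.000000
PHEN	IPRO	4	13	0.307692
PHEN	MGI	0	13	0.000000
ACET	HEXA	1	16	0.062500
ACET	IPRO	4	10	0.400000
ACET	MGI	0	10	0.000000
HEXA	IPRO	2	15	0.133333
HEXA	MGI	0	13	0.000000
IPRO	MGI	0	10	0.000000
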