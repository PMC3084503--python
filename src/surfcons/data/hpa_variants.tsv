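# Human platelet alloantigens (HPA-1 .. HPA-17): published per-antigen
# annotations transcribed from the primary serology/structure literature.
# sasa column: semicolon-separated value:structure pairs (percent relative
# accessibility in the named crystal structure or homology model);
# sentinel "disordered:<id>" = position unresolved in that structure;
# empty = no structure available for the carrier protein.
# conservation_grade: published 1-9 grade (1 = variable, 9 = conserved).
id	gene	substitution	group	numbering_scheme	domain	sasa	conservation_grade	secondary_structure	note
HPA-1	ITGB3	Leu33Pro	hpa	mature	PSI	98:3FCS;100:3FCU	1	loop	third allele Leu33Val
HPA-2	GP1BA	Thr145Met	hpa	mature	LRR	67:1SQ0	3	loop
HPA-3	ITGA2B	Ile843Ser	hpa	mature	Calf2	disordered:3FCS	2	loop
HPA-4	ITGB3	Arg143Gln	hpa	mature	betaA	62:1JV2;43:1TXV;76:3FCS;43:3FCU	2	alpha-helix
HPA-5	ITGA2	Lys505Glu	hpa	mature	beta-propeller	73:alpha2-model	1	loop	homology model
HPA-6	ITGB3	Arg489Gln	hpa	mature	EGF-1	76:3FCS	1
HPA-7	ITGB3	Pro407Ala	hpa	mature	hybrid	27:1JV2;17:1TXV;8:3FCS	6	loop
HPA-8	ITGB3	Arg636Cys	hpa	mature	betaTD	59:1JV2;66:3FCS	1	loop
HPA-9	ITGA2B	Val837Met	hpa	mature	Calf2	40:3FCS	6	loop
HPA-10	ITGB3	Arg62Gln	hpa	mature	hybrid	32:1JV2;63:1TXV;71:3FCS;69:3FCU	1	beta-sheet
HPA-11	ITGB3	Arg633His	hpa	mature	betaTD	17:1JV2;53:3FCS	1	loop
HPA-12	GP1BB	Gly15Glu	hpa	mature			2		no structure
HPA-13	ITGA2	Thr799Met	hpa	mature	Calf1	32:alpha2-model	6	beta-sheet	homology model
HPA-14	ITGB3	Lys611del	hpa	mature	betaTD	15:1JV2;41:3FCS	4	alpha-helix	single-residue deletion
HPA-15	CD109	Tyr703Ser	hpa	precursor			4		no structure; residue 682 in mature protein
HPA-16	ITGB3	Thr140Ile	hpa	mature	betaA	51:1JV2;31:1TXV;55:3FCS;60:3FCU	1	alpha-helix
HPA-17	ITGA2	Thr1087Met	hpa	mature	Calf2	53:alpha2-model	5	beta-sheet	homology model
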