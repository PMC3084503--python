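# Validated nonsynonymous SNPs in integrin alphaIIb/beta3 with no reported
# immunogenicity, with published per-structure relative accessibility and
# 1-9 conservation grades.  Same column conventions as hpa_variants.tsv.
id	gene	substitution	group	numbering_scheme	domain	sasa	conservation_grade	secondary_structure	note
SNP-1	ITGB3	Leu40Arg	neutral	mature	PSI	28.8:3FCS;20.7:3FCU	4		rs36080296
SNP-2	ITGB3	Leu90Phe	neutral	mature	hybrid	0.56:3FCS;0.61:3FCU;1.27:1JV2	6		rs72547409
SNP-3	ITGB3	Val427Ile	neutral	mature	hybrid	0:3FCS;0:3FCU;0:1JV2	6		rs5921
SNP-4	ITGB3	Glu628Lys	neutral	mature	betaTD	66.5:3FCS;45.6:1JV2	1		rs70940817
SNP-5	ITGA2B	Leu116Val	neutral	mature	beta-propeller	34.9:3FCS;35.8:3FCU	1
SNP-6	ITGA2B	Val618Leu	neutral	mature	Calf1	16.8:3FCS	1		rs7207402
SNP-7	ITGA2B	Ser725Arg	neutral	mature	Calf1	11.6:3FCS	9		rs74563314
SNP-8	ITGA2B	Tyr937Asn	neutral	mature	Calf2	23.7:3FCS	4		rs2934
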