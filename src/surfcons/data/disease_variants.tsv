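# Disease-causing missense mutations: Glanzmann thrombasthenia (integrin
# alphaIIb/beta3) and Bernard-Soulier syndrome (GPIb-alpha), with published
# per-structure relative accessibility and 1-9 conservation grades.
# Same column conventions as hpa_variants.tsv.
id	gene	substitution	group	numbering_scheme	domain	sasa	conservation_grade	secondary_structure	note
GT-1	ITGB3	Cys13Gly	disease	mature	PSI	0.3:3FCS;0.64:3FCU	9		GT
GT-2	ITGB3	Arg93Glu	disease	mature	hybrid	1.4:3FCS;1.4:3FCU;14.5:1JV2	9		GT
GT-3	ITGB3	Leu117Trp	disease	mature	betaA	0:3FCS;0:3FCU;0:1JV2	9		GT
GT-4	ITGB3	His192Tyr	disease	mature	betaA	4.3:3FCS;1.9:3FCU;1.7:1JV2	9		GT
GT-5	ITGB3	Val395Met	disease	mature	hybrid	3.7:3FCS;1.4:3FCU;4.3:1JV2	8		GT
GT-6	ITGB3	Cys549Arg	disease	mature	EGF-3	13.97:3FCS;23.29:1JV2	9		GT
GT-7	ITGA2B	Asn2Asp	disease	mature	beta-propeller	0.55:3FCS;4.93:3FCU	9		GT
GT-8	ITGA2B	Ala108Val	disease	mature	beta-propeller	0:3FCS;0:3FCU	8		GT
GT-9	ITGA2B	Phe171Cys	disease	mature	beta-propeller	24.2:3FCS;23.5:3FCU	8		GT; 1% exposed in the heterodimer complex (interface with beta3)
GT-10	ITGA2B	Gly265Arg	disease	mature	beta-propeller	0.1:3FCS;0:3FCU	9		GT
GT-11	ITGA2B	Gly349Val	disease	mature	beta-propeller	8.5:3FCS;7.8:3FCU	8		GT
GT-12	ITGA2B	His782Asn	disease	mature	Calf2	5.02:3FCS	6		GT
BSS-1	GP1BA	Trp207Gly	disease	mature	S-S loop	0:1SQ0	5		BSS
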