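# Curated numbering map: how mature-protein variant positions translate to
# structure author numbering and to conservation-profile columns.
#   author position in structure = variant position + position_offset
#   precursor position           = mature position + signal_peptide_offset
# position_offset 0 reflects mature-protein author numbering in the platelet
# receptor crystal structures; every mapping is validated at run time by the
# wild-type identity check, never trusted silently.
# signal_peptide_offset provenance: UniProt signal-peptide annotations
# (ITB3_HUMAN 26, ITA2B_HUMAN 31, GP1BA_HUMAN 16, GP1BB_HUMAN 25,
#  ITA2_HUMAN 29, CD109_HUMAN 21; CD109 Tyr703 precursor = 682 mature).
gene	structure_id	chain	position_offset	signal_peptide_offset	msa_id	msa_offset
ITGB3	1JV2	B	0	26	beta-integrins	0
ITGB3	3FCS	B	0	26	beta-integrins	0
ITGB3	3FCU	B	0	26	beta-integrins	0
ITGB3	1TXV	B	0	26	beta-integrins	0
ITGA2B	3FCS	A	0	31	alpha-integrins	0
ITGA2B	3FCU	A	0	31	alpha-integrins	0
GP1BA	1SQ0	B	0	16	lrr-family	0
GP1BB	-	-	0	25	lrr-family	0
ITGA2	-	-	0	29	alpha-integrins	0
CD109	-	-	0	21	cd109-family	0
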