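# Heavy-atom van der Waals radii (Å), element-keyed.
# C/N/O/S values after Chothia, J Mol Biol 105:1-12 (1976), as used by the
# NACCESS family of accessibility programs; P and Se after Bondi,
# J Phys Chem 68:441-451 (1964).
# element	radius_A
C	1.76
N	1.65
O	1.40
S	1.85
P	1.90
SE	1.90
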