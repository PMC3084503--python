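"""Amino-acid alphabets and code conversions."""

#: canonical one-letter ordering used for all 20-state vectors/matrices
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

STANDARD_RESIDUES = frozenset(ONE_TO_THREE.values())

GAP_CHARS = frozenset("-.")
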