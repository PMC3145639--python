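"""The 20-letter amino-acid alphabet and kinase-type phospho alphabets.

Residue order is alphabetical one-letter code (A..Y); every 20-vector and
20x7 matrix in the package indexes rows in this order.
"""

AA20: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA20)}

#: Padding symbol used for substrate windows running past a terminus.
PAD: str = "X"

#: Ambiguity / non-standard one-letter codes that may appear in inputs.
NONSTANDARD: frozenset[str] = frozenset("BZXUOJ")

SERINE_THREONINE = "serine/threonine"
CMGC = "CMGC"
TYROSINE = "tyrosine"
KINASE_TYPES: tuple[str, ...] = (SERINE_THREONINE, CMGC, TYROSINE)

#: Acceptor residues allowed at the phospho position for each kinase type.
#: CMGC kinases are serine/threonine-directed but form their own matching
#: class because their specificity-determining residues differ.
PHOSPHO_ALPHABET: dict[str, str] = {
    SERINE_THREONINE: "ST",
    CMGC: "ST",
    TYROSINE: "Y",
}
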