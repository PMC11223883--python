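"""Shared amino-acid constants: alphabets, hydropathy, maximal ASA, N-end rule.

All tables are for the 20 canonical L-amino acids in 1-letter code.
"""

from __future__ import annotations

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
CANONICAL_SET = frozenset(CANONICAL_AA)

# Non-canonical 1-letter codes that can occur in real-world FASTA files.
AMBIGUOUS_AA = frozenset("BJOUXZ")

# Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Maximal accessible surface area per residue type (A^2), Sander convention,
# used to normalize absolute ASA to relative solvent accessibility (RSA).
SANDER_MAX_ASA = {
    "A": 106.0, "R": 248.0, "N": 157.0, "D": 163.0, "C": 135.0,
    "Q": 198.0, "E": 194.0, "G": 84.0, "H": 184.0, "I": 169.0,
    "L": 164.0, "K": 205.0, "M": 188.0, "F": 197.0, "P": 136.0,
    "S": 130.0, "T": 142.0, "W": 227.0, "Y": 222.0, "V": 142.0,
}

# Arg/N-degron pathway classification of the N-terminal residue.
# type-1 primary: basic; type-2 primary: bulky hydrophobic; secondary:
# arginylation substrates; tertiary: deamidation/oxidation substrates.
N_END_RULE_CLASSES = {
    "type1_primary": frozenset("RKH"),
    "type2_primary": frozenset("FWYLI"),
    "secondary": frozenset("DE"),
    "tertiary": frozenset("NQC"),
}


def gravy(sequence: str) -> float:
    """Grand average of hydropathy (mean Kyte-Doolittle) of ``sequence``."""
    if not sequence:
        raise ValueError("cannot compute gravy of an empty sequence")
    try:
        return sum(KYTE_DOOLITTLE[a] for a in sequence) / len(sequence)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc.args[0]!r}") from None
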