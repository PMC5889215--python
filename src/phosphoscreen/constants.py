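"""Shared constants: residue alphabet, position labels, scaffold flanks, codons.

Peptides in the library are 15-mers with the target tyrosine at the centre.
Positions are labelled -7..+7 with 0 at the central tyrosine; 1-based string
position 8 corresponds to position 0.
"""

from __future__ import annotations

# Fixed row order for all residue x position matrices.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

PEPTIDE_LENGTH: int = 15
CENTER_INDEX: int = 7  # 0-based index of the central tyrosine
POSITIONS: tuple[int, ...] = tuple(range(-7, 8))

# Scaffold-fusion flanks appended to every 45-nt peptide-coding sequence.
FLANK_5: str = "GCTGGCCAGTCTGGCCAG"
FLANK_3: str = "GGAGGGCAGTCTGGGCAGTCTG"

# Most-prevalent codon per amino acid in E. coli K-12. The encoding rule is
# "one fixed codon per residue"; users may override with their own table.
ECOLI_PREFERRED_CODONS: dict[str, str] = {
    "A": "GCG",
    "C": "TGC",
    "D": "GAT",
    "E": "GAA",
    "F": "TTT",
    "G": "GGC",
    "H": "CAT",
    "I": "ATT",
    "K": "AAA",
    "L": "CTG",
    "M": "ATG",
    "N": "AAC",
    "P": "CCG",
    "Q": "CAG",
    "R": "CGC",
    "S": "AGC",
    "T": "ACC",
    "V": "GTG",
    "W": "TGG",
    "Y": "TAT",
}


def pos_to_index(position: int) -> int:
    """Map a -7..+7 position label to a 0-based index into a 15-mer."""
    if not -7 <= position <= 7:
        raise ValueError(f"position {position} outside -7..+7")
    return position + CENTER_INDEX


def index_to_pos(index: int) -> int:
    """Map a 0-based 15-mer index to its -7..+7 position label."""
    if not 0 <= index < PEPTIDE_LENGTH:
        raise ValueError(f"index {index} outside 0..14")
    return index - CENTER_INDEX
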