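"""Amino-acid alphabet, substitution matrix and background composition.

The 20 standard residues are kept in alphabetical one-letter order
everywhere (matrix columns, encodings, PSSM output).  'X' denotes an
unknown/averaged residue: peptide arrays sometimes exclude a residue from
synthesis (e.g. lysine, whose free epsilon-amino group would confound
amine-labelling chemistry), and evaluation data may carry ambiguity codes.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard amino acids, alphabetical single-letter order.
AA_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AA_ORDER)}

#: Average amino-acid composition of a large curated protein database
#: (Swiss-Prot release statistics), used both to generate random
#: "naturally occurring" background peptides and as the null model q_a of
#: the log-odds matrix.  Values are relative frequencies, renormalised to
#: sum to exactly 1.
_SWISSPROT_PERCENT = {
    "A": 8.25, "R": 5.53, "N": 4.06, "D": 5.45, "C": 1.38,
    "Q": 3.93, "E": 6.75, "G": 7.07, "H": 2.27, "I": 5.96,
    "L": 9.66, "K": 5.84, "M": 2.42, "F": 3.86, "P": 4.70,
    "S": 6.56, "T": 5.34, "W": 1.08, "Y": 2.92, "V": 6.87,
}

BACKGROUND_FREQS: np.ndarray = np.array(
    [_SWISSPROT_PERCENT[aa] for aa in AA_ORDER], dtype=np.float64
)
BACKGROUND_FREQS /= BACKGROUND_FREQS.sum()


def _blosum62_matrix() -> np.ndarray:
    """BLOSUM62 scores as a 20x20 array in AA_ORDER, from biopython."""
    blosum = substitution_matrices.load("BLOSUM62")
    mat = np.empty((20, 20), dtype=np.float64)
    for i, a in enumerate(AA_ORDER):
        for j, b in enumerate(AA_ORDER):
            mat[i, j] = blosum[a][b]
    return mat


BLOSUM62: np.ndarray = _blosum62_matrix()

#: Logo colouring by chemical property (polar green / amide pink /
#: basic blue / acidic red / hydrophobic black).
COLOR_CLASSES: dict[str, str] = {}
for _aa in "CGSTY":
    COLOR_CLASSES[_aa] = "green"
for _aa in "NQ":
    COLOR_CLASSES[_aa] = "pink"
for _aa in "KRH":
    COLOR_CLASSES[_aa] = "blue"
for _aa in "DE":
    COLOR_CLASSES[_aa] = "red"
for _aa in "ALIVFMPW":
    COLOR_CLASSES[_aa] = "black"


def validate_peptide(peptide: str, context: str = "peptide") -> str:
    """Uppercase and validate a peptide string against the alphabet (+X).

    Raises ValueError naming the peptide and the offending character.
    """
    pep = peptide.strip().upper()
    if not pep:
        raise ValueError(f"empty {context}")
    for ch in pep:
        if ch not in AA_INDEX and ch != "X":
            raise ValueError(
                f"illegal character {ch!r} in {context} {pep!r}: "
                f"allowed letters are {AA_ORDER} and X"
            )
    return pep


def peptides_to_codes(peptides: list[str]) -> list[np.ndarray]:
    """Integer-encode peptides (A..Y -> 0..19, X -> 20) as int64 arrays."""
    lut = np.full(128, -1, dtype=np.int64)
    for aa, i in AA_INDEX.items():
        lut[ord(aa)] = i
    lut[ord("X")] = 20
    out = []
    for pep in peptides:
        codes = lut[np.frombuffer(pep.encode("ascii"), dtype=np.uint8)]
        if (codes < 0).any():
            bad = pep[int(np.argmax(codes < 0))]
            raise ValueError(f"illegal character {bad!r} in peptide {pep!r}")
        out.append(codes)
    return out
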