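"""The 20-letter amino-acid alphabet and the terminal pad symbol.

All encoders in this package index amino acids in the fixed order
``ACDEFGHIKLMNPQRSTVWY``.  Window positions that fall past a protein
terminus carry the pad symbol ``X``, which every encoder treats as an
information-free placeholder (all-zero one-hot block, property value 0,
substitution similarity 0).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
PAD: str = "X"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: integer code used for the pad symbol in vectorized encoders
PAD_CODE: int = 20


def encode_residues(residues: str) -> list[int]:
    """Map a residue string to integer codes (0-19 for amino acids, 20 for pad).

    Raises
    ------
    ValueError
        If a character is neither a standard amino acid nor the pad symbol.
    """
    codes = []
    for ch in residues:
        if ch == PAD:
            codes.append(PAD_CODE)
        elif ch in AA_INDEX:
            codes.append(AA_INDEX[ch])
        else:
            raise ValueError(f"illegal residue character {ch!r}")
    return codes


def validate_sequence(sequence: str, *, allow_pad: bool = True) -> None:
    """Raise ``ValueError`` on characters outside the alphabet (plus 'X' if allowed)."""
    allowed = set(AMINO_ACIDS) | ({PAD} if allow_pad else set())
    bad = sorted(set(sequence) - allowed)
    if bad:
        raise ValueError(f"illegal characters in sequence: {bad}")
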