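"""The residue alphabet shared by every module.

The method's information measures assume a fixed 20-letter amino-acid
alphabet; ambiguous one-letter codes (B, Z, X, U, O) are rejected at parse
time rather than silently folded into a canonical residue.
"""

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
"""Canonical order used for every probability vector in the package."""

AA_TO_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

N_RESIDUES: int = 20

GAP: str = "-"

GAP_ALIASES: frozenset[str] = frozenset({"-", "."})

GAP_CODE: int = -1
"""Integer code used for gaps in encoded alignments."""


def encode_sequence(seq: str) -> list[int]:
    """Map an aligned sequence to integer codes (gap -> GAP_CODE).

    Raises KeyError on characters outside the alphabet; callers that need a
    positioned error message should validate first.
    """
    return [GAP_CODE if c in GAP_ALIASES else AA_TO_INDEX[c] for c in seq]
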