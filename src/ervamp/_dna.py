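"""Low-level nucleotide utilities: IUPAC codes, bit encoding, reverse complement.

Bases are encoded as 4-bit flags (A=1, C=2, G=4, T=8) so that an IUPAC
primer base matches a genome base iff ``primer_mask & base_bits != 0``.
Characters outside the IUPAC alphabet encode to 0 and therefore match
nothing.
"""

from __future__ import annotations

import numpy as np

IUPAC_SETS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}

#: bitmask for every IUPAC code (mask of the set of bases it stands for)
IUPAC_MASKS: dict[str, int] = {
    code: sum(_BITS[b] for b in bases) for code, bases in IUPAC_SETS.items()
}

_COMP = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}
_COMP_TABLE = str.maketrans(
    "".join(_COMP) + "".join(_COMP).lower(),
    "".join(_COMP.values()) + "".join(_COMP.values()).lower(),
)

# base -> 4-bit code lookup for fast array encoding (uppercase + lowercase)
_ENCODE_LUT = np.zeros(256, dtype=np.uint8)
for _b, _v in _BITS.items():
    _ENCODE_LUT[ord(_b)] = _v
    _ENCODE_LUT[ord(_b.lower())] = _v


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware (e.g. R<->Y, K<->M)."""
    return seq.translate(_COMP_TABLE)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode A/C/G/T (case-insensitive) to uint8 bit codes; other chars -> 0."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def primer_masks(primer: str) -> np.ndarray:
    """Per-position IUPAC bitmasks for a primer string (raises on bad chars)."""
    try:
        return np.array([IUPAC_MASKS[b] for b in primer.upper()], dtype=np.uint8)
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character in primer: {exc.args[0]!r}") from None


def validate_iupac(seq: str, what: str = "sequence") -> None:
    bad = set(seq.upper()) - set(IUPAC_SETS)
    if bad:
        raise ValueError(f"non-IUPAC characters in {what}: {sorted(bad)}")
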