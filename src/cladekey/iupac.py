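"""Nucleotide alphabet utilities: IUPAC codes, bitmask encoding, complements.

Every sequence entering the package is normalised to uppercase with U→T.
Bases are encoded as 4-bit masks (A=1, C=2, G=4, T=8); an IUPAC ambiguity
code is the OR of its expansion and a gap character encodes to 0, so
"state s is carried by code x" is the bit test ``mask(s) & mask(x)``.
"""

from __future__ import annotations

import numpy as np

GAP_CHARS = "-."

_EXPANSION = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: IUPAC code -> 4-bit mask over {A,C,G,T}; gaps map to 0.
MASK = {c: sum(_BASE_BIT[b] for b in exp) for c, exp in _EXPANSION.items()}
for _g in GAP_CHARS:
    MASK[_g] = 0

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-.", "TGCAYRSWMKVHDBN-."
)

#: uint8 lookup table from ASCII ordinal to bitmask (255 = invalid).
_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _m in MASK.items():
    _LUT[ord(_c)] = _m


def normalize(seq: str) -> str:
    """Uppercase a sequence and replace U with T."""
    return seq.upper().replace("U", "T")


def validate(seq: str, *, allow_gaps: bool = True, name: str = "sequence") -> None:
    allowed = set(MASK) if allow_gaps else set(MASK) - set(GAP_CHARS)
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"{name} contains characters outside the IUPAC nucleotide "
            f"alphabet: {sorted(bad)}"
        )


def encode(seq: str) -> np.ndarray:
    """Encode a normalised sequence as a uint8 bitmask array."""
    arr = _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        validate(seq)  # raises with a readable message
    return arr


def compatible(a: str, b: str) -> bool:
    """True when the IUPAC expansions of two codes intersect.

    Gaps have an empty expansion and are compatible with nothing,
    including other gaps.
    """
    return bool(MASK[a] & MASK[b])


def is_unambiguous(c: str) -> bool:
    return c in _BASE_BIT


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def degap(seq: str) -> str:
    for g in GAP_CHARS:
        seq = seq.replace(g, "")
    return seq
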