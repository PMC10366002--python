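"""Shared low-level sequence primitives.

DNA is handled as upper-case text over {A,C,G,T,N} at the API surface and as
numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3, N=4) inside the scanners.
All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive convention of GenBank/GFF3/VCF happens at the I/O boundary.
"""

from __future__ import annotations

import numpy as np

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# IUPAC nucleotide codes -> set of concrete bases they stand for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENC_TABLE[ord(_b)] = _c
    _ENC_TABLE[ord(_b.lower())] = _c

# complement in code space; N stays N
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode DNA text to a uint8 code array (unknown letters become N)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes][::-1]


def iupac_match_table(pattern: str) -> np.ndarray:
    """Boolean table ``t[i, code]`` — does pattern position i accept that base.

    N in the *genome* (code 4) never matches any pattern position, including
    pattern N: ambiguous bases never qualify as a PAM.
    """
    pattern = pattern.upper()
    table = np.zeros((len(pattern), 5), dtype=bool)
    for i, ch in enumerate(pattern):
        try:
            allowed = IUPAC[ch]
        except KeyError:
            raise ValueError(f"invalid IUPAC code {ch!r} in pattern {pattern!r}")
        for base in allowed:
            table[i, _CODE[base]] = True
    return table


def iupac_matches(pattern: str, seq: str) -> bool:
    """Character-wise IUPAC match of ``seq`` against ``pattern`` (same length)."""
    if len(pattern) != len(seq):
        return False
    for p, s in zip(pattern.upper(), seq.upper()):
        if s == "N" or s not in IUPAC.get(p, ""):
            return False
    return True


def pattern_subsumes(p1: str, p2: str) -> bool:
    """True when every match of ``p1`` is a match of ``p2`` (e.g. NGG vs NG)."""
    if len(p2) > len(p1):
        return False
    return all(set(IUPAC[a]) <= set(IUPAC[b]) for a, b in zip(p1.upper(), p2.upper()))


def validate_dna(seq: str, *, allow_n: bool = True, what: str = "sequence") -> str:
    seq = seq.upper()
    allowed = set("ACGTN" if allow_n else "ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"{what} contains non-DNA characters: {sorted(bad)}")
    return seq
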