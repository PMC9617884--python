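"""Low-level DNA sequence helpers shared across the package.

All sequences are uppercase strings over {A, C, G, T, N}. Ambiguity codes
other than N in *input* data are mapped to N on read; N never counts as a
match, not even against another N.
"""

from __future__ import annotations

import math

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# every non-ACGT letter (IUPAC ambiguity or junk) collapses to N
_NORMALIZE = str.maketrans(
    "acgtn" + "RYSWKMBDHVryswkmbdhvUu-. ",
    "ACGTN" + "N" * 25,
)

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_SET_TO_IUPAC = {v: k for k, v in IUPAC_SETS.items()}


def revcomp(seq: str) -> str:
    """Reverse complement; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_dna(seq: str) -> str:
    """Uppercase and collapse any non-ACGT letter to N."""
    return seq.translate(_NORMALIZE)


def iupac_for_bases(bases) -> str:
    """IUPAC letter for a non-empty subset of {A,C,G,T}."""
    key = frozenset(bases)
    if not key or not key <= frozenset("ACGT"):
        raise ValueError(f"not a valid base set: {bases!r}")
    return _SET_TO_IUPAC[key]


def iupac_matches(pam: str, seq: str) -> bool:
    """True iff ``seq`` (plain DNA, same length) is admitted by IUPAC ``pam``.

    An N in the target sequence is never admitted except by pam N.
    """
    if len(pam) != len(seq):
        return False
    for p, s in zip(pam, seq):
        if p == "N":
            continue
        if s not in IUPAC_SETS[p]:
            return False
    return True


def information_bits(freqs) -> float:
    """Information content 2 + sum(p * log2 p) of a 4-vector of frequencies."""
    info = 2.0
    for p in freqs:
        if p > 0.0:
            info += p * math.log2(p)
    return info
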