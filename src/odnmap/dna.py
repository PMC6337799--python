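"""Small DNA utilities shared across the pipeline.

Sequences are plain upper-case strings over {A,C,G,T,N}; coordinates are
0-based half-open throughout the library.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: IUPAC nucleotide codes -> set of concrete bases they admit.
IUPAC: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    # pattern N means "any base": an ambiguous genome N satisfies it, but
    # never satisfies any concrete (non-N) symbol.
    "N": frozenset("ACGTN"),
}

DNA_BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (IUPAC letters outside ACGTN not handled)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming_matches(a: str, b: str) -> int:
    """Number of positions where equal-length strings agree."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b))


def hamming_distance(a: str, b: str) -> int:
    return len(a) - hamming_matches(a, b)


def matches_iupac(seq: str, pattern: str) -> bool:
    """True iff ``seq`` satisfies the IUPAC ``pattern`` position by position.

    An ambiguous genome base N never satisfies a non-N pattern symbol
    (conservative: an unknown base is not evidence of a PAM).
    """
    if len(seq) != len(pattern):
        return False
    for base, code in zip(seq, pattern):
        allowed = IUPAC.get(code)
        if allowed is None:
            raise ValueError(f"not an IUPAC code: {code!r}")
        if base not in allowed:
            return False
    return True


def validate_alphabet(seq: str, alphabet: str, what: str = "sequence") -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"{what} contains invalid characters {sorted(bad)!r}")


def seq_to_array(seq: str) -> np.ndarray:
    """Byte view of a sequence for vectorized comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def iupac_lookup(code: str) -> np.ndarray:
    """256-entry boolean table: table[ord(base)] == base satisfies ``code``."""
    table = np.zeros(256, dtype=bool)
    for base in IUPAC[code]:
        table[ord(base)] = True
    return table
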