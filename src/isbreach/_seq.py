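"""Low-level DNA string utilities shared across modules.

All sequences are plain uppercase Python strings; coordinates are
0-based half-open unless a function says otherwise.
"""

from __future__ import annotations

import re
from typing import Iterator

DNA_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

#: IUPAC degenerate code -> set of concrete bases.
IUPAC_SETS = {
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

#: base-set (as a sorted tuple) -> IUPAC letter, inverse of IUPAC_SETS.
SETS_TO_IUPAC = {tuple(sorted(v)): k for k, v in IUPAC_SETS.items()}


def revcomp(seq: str) -> str:
    """Reverse complement; degenerate IUPAC letters are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize(seq: str) -> str:
    """Uppercase a sequence and map U to T. No alphabet check."""
    return seq.upper().replace("U", "T")


def validate_dna(seq: str, name: str = "sequence") -> None:
    """Raise ValueError naming the first non-ACGT position (1-based)."""
    for i, base in enumerate(seq):
        if base not in DNA_ALPHABET:
            raise ValueError(
                f"non-ACGT character {base!r} in {name} at position {i + 1}"
            )


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC pattern into an overlapping-match regex.

    The regex uses a lookahead capture so every window, including
    overlapping ones, is reported by finditer.
    """
    parts = []
    for letter in pattern.upper():
        try:
            bases = IUPAC_SETS[letter]
        except KeyError:
            raise ValueError(f"invalid IUPAC letter {letter!r} in pattern {pattern!r}")
        parts.append(letter if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return re.compile(r"(?=(" + "".join(parts) + r"))")


def matches_iupac(seq: str, pattern: str) -> bool:
    """Positionwise IUPAC match of a full-length window."""
    if len(seq) != len(pattern):
        return False
    for base, letter in zip(seq, pattern.upper()):
        if letter not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC letter {letter!r} in pattern {pattern!r}")
        if base not in IUPAC_SETS[letter]:
            return False
    return True


def find_all(haystack: str, needle: str) -> Iterator[int]:
    """Yield every (possibly overlapping) start offset of needle."""
    if not needle:
        return
    i = haystack.find(needle)
    while i != -1:
        yield i
        i = haystack.find(needle, i + 1)


def gc_fraction(seq: str) -> float:
    """Fraction of G+C over the sequence length (S counts as G/C)."""
    if not seq:
        return 0.0
    return sum(seq.count(b) for b in "GCS") / len(seq)


def random_dna(n: int, rng, gc: float = 0.5) -> str:
    """Random DNA of length n at the given expected GC, from a numpy Generator."""
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    return "".join(rng.choice(("A", "C", "G", "T"), size=n, p=(p_at, p_gc, p_gc, p_at)))
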