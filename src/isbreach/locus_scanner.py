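"""Exact full-length scanning of catalog elements against target sequences.

Matching is literal string equality (the 100% identity / 100% coverage
retention rule), so no alignment machinery is involved and "N" in a
target can never match. Both strands are always scanned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Tuple

from ._seq import find_all, revcomp
from .sequence_io import ISCatalog


@dataclass(frozen=True)
class ISHit:
    """An exact, full-length occurrence of a catalog element.

    ``start``/``end`` are 0-based half-open on the + strand of the
    target; for strand "-" the reverse complement of the target
    subsequence equals the element.
    """

    element_name: str
    seq_id: str
    start: int
    end: int
    strand: str
    target_length: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid hit interval [{self.start}, {self.end})")


class Flanks(NamedTuple):
    upstream: str
    downstream: str
    upstream_truncated: bool
    downstream_truncated: bool


def find_exact_copies(
    catalog: ISCatalog,
    targets: Dict[str, str],
    circular: bool = False,
) -> List[ISHit]:
    """All maximal exact full-length occurrences of every element, both strands.

    Overlapping hits are all reported. Order is deterministic:
    (seq_id, start, element_name, strand). With ``circular`` the target
    is virtually extended by its first len(element)-1 bases so matches
    spanning the origin are found (their ``end`` may exceed
    ``target_length``).
    """
    if not targets:
        raise ValueError("no target sequences supplied")
    hits: List[ISHit] = []
    for seq_id, target in targets.items():
        n = len(target)
        for element in catalog:
            # a palindromic element legitimately hits both strands at one spot
            probes = [(element.sequence, "+"), (revcomp(element.sequence), "-")]
            for probe, strand in probes:
                hay = target
                if circular and n >= len(probe):
                    hay = target + target[: len(probe) - 1]
                for start in find_all(hay, probe):
                    if start >= n:
                        continue
                    hits.append(
                        ISHit(
                            element_name=element.name,
                            seq_id=seq_id,
                            start=start,
                            end=start + len(probe),
                            strand=strand,
                            target_length=n,
                        )
                    )
    return sorted(set(hits), key=lambda h: (h.seq_id, h.start, h.element_name, h.strand))


def extract_flanks(
    target_sequence: str,
    interval: Tuple[int, int],
    up: int,
    down: int,
) -> Flanks:
    """Bases immediately 5' and 3' of an interval on the + strand.

    Windows that would run past a sequence boundary are truncated and
    flagged rather than padded.
    """
    start, end = interval
    if up < 0 or down < 0:
        raise ValueError("flank lengths must be non-negative")
    if not (0 <= start < end <= len(target_sequence)):
        raise ValueError(
            f"interval [{start}, {end}) outside sequence of length {len(target_sequence)}"
        )
    up_start = max(0, start - up)
    upstream = target_sequence[up_start:start]
    downstream = target_sequence[end : end + down]
    return Flanks(
        upstream=upstream,
        downstream=downstream,
        upstream_truncated=len(upstream) < up,
        downstream_truncated=len(downstream) < down,
    )


def hits_to_rows(hits: List[ISHit]) -> List[dict]:
    """Hit table rows with 1-based inclusive file coordinates."""
    return [
        {
            "element": h.element_name,
            "seq_id": h.seq_id,
            "start_1based": h.start + 1,
            "end_1based": h.end,
            "strand": h.strand,
        }
        for h in hits
    ]
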