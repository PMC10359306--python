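"""Direct-repeat (target-site duplication) calling around element hits.

The caller generalizes a fixed-length flanking-repeat search: it tests
every k in a range and reports the largest k for which the k bases
immediately 5' of the element equal the k bases immediately 3' of it,
exactly, on the + strand of the target. A canonical-only mode restricts
candidate k to an element's characteristic lengths, reproducing a
fixed-length scan.

Short duplications arise by chance at roughly 4^-k per boundary; that
probability is surfaced on every call rather than hidden behind a
filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import FrozenSet, Iterable, Optional, Tuple

from ._seq import DNA_ALPHABET
from .locus_scanner import ISHit
from .sequence_io import ISElement

STATUS_CANONICAL = "canonical"
STATUS_ABERRANT = "aberrant"
STATUS_NONE = "none"


@dataclass
class TSDCall:
    """The duplication (or absence of one) flanking a single hit."""

    hit: ISHit
    k: int
    tsd_sequence: str
    upstream_interval: Optional[Tuple[int, int]] = None
    downstream_interval: Optional[Tuple[int, int]] = None
    status: str = STATUS_NONE

    def __post_init__(self):
        if self.k > 0:
            if len(self.tsd_sequence) != self.k:
                raise ValueError("tsd_sequence length disagrees with k")
            if self.upstream_interval is None or self.downstream_interval is None:
                raise ValueError("repeat-copy intervals required when k > 0")
        elif self.status != STATUS_NONE:
            raise ValueError("status must be 'none' when k == 0")

    @property
    def random_match_probability(self) -> float:
        """Chance of a spurious exact k-mer duplication at one boundary."""
        return 4.0 ** -self.k if self.k > 0 else 1.0


def call_tsd(
    target_sequence: str,
    hit: ISHit,
    k_min: int = 4,
    k_max: int = 25,
    canonical_set: Optional[Iterable[int]] = None,
    canonical_only: bool = False,
) -> TSDCall:
    """Longest-k direct-repeat call for one hit.

    Candidate lengths run from k_max down to k_min (or, with
    ``canonical_only``, over ``canonical_set`` descending). Candidates
    whose windows extend past a sequence end are skipped, not errors;
    windows containing non-ACGT letters never match. Comparison is on
    the + strand regardless of hit strand.
    """
    if not 1 <= k_min <= k_max <= 30:
        raise ValueError(f"invalid k range [{k_min}, {k_max}]")
    if hit.end > len(target_sequence):
        raise ValueError("hit extends past target sequence")
    canon: FrozenSet[int] = frozenset(canonical_set or ())
    if canonical_only:
        if not canon:
            raise ValueError("canonical_only requires a canonical_set")
        candidates = sorted(canon, reverse=True)
    else:
        candidates = range(k_max, k_min - 1, -1)

    for k in candidates:
        if hit.start - k < 0 or hit.end + k > len(target_sequence):
            continue
        up = target_sequence[hit.start - k : hit.start]
        down = target_sequence[hit.end : hit.end + k]
        if up == down and set(up) <= DNA_ALPHABET:
            status = STATUS_CANONICAL if k in canon else STATUS_ABERRANT
            if not canon:
                status = STATUS_ABERRANT
            return TSDCall(
                hit=hit,
                k=k,
                tsd_sequence=up,
                upstream_interval=(hit.start - k, hit.start),
                downstream_interval=(hit.end, hit.end + k),
                status=status,
            )
    return TSDCall(hit=hit, k=0, tsd_sequence="", status=STATUS_NONE)


def classify_tsd(call: TSDCall, element: ISElement) -> str:
    """Re-classify a call against an element's canonical length set.

    Returns the status string and updates ``call.status`` in place.
    """
    if call.k == 0:
        status = STATUS_NONE
    elif call.k in element.canonical_tsd_lengths:
        status = STATUS_CANONICAL
    else:
        status = STATUS_ABERRANT
    call.status = status
    return status


def calls_to_rows(calls) -> list:
    """TSD-call table rows with 1-based inclusive file coordinates."""
    return [
        {
            "element": c.hit.element_name,
            "seq_id": c.hit.seq_id,
            "element_start_1based": c.hit.start + 1,
            "element_end_1based": c.hit.end,
            "strand": c.hit.strand,
            "k": c.k,
            "tsd_sequence": c.tsd_sequence,
            "status": c.status,
            "random_match_probability": c.random_match_probability,
        }
        for c in calls
    ]
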