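"""Exact spacer-to-protospacer matching with optional PAM checking.

Matching is the same 100% identity / 100% coverage rule as element
scanning; PAM checking is layered on top and reported separately, never
used to discard a match.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

from ._seq import find_all, matches_iupac, revcomp, validate_dna

PAM_SIDES = {"5prime", "3prime"}


@dataclass(frozen=True)
class ProtospacerMatch:
    spacer_id: str
    target_seq_id: str
    start: int  # 0-based half-open, + strand of target
    end: int
    strand: str
    pam_ok: Optional[bool] = None
    pam_observed: str = ""
    note: str = ""


def match_spacers(
    spacers: Dict[str, str],
    targets: Dict[str, str],
    pam: Optional[Tuple[str, str]] = None,
) -> List[ProtospacerMatch]:
    """All exact full-length spacer occurrences on both target strands.

    ``pam`` is (IUPAC string, side) with side in {"5prime", "3prime"},
    expressed in protospacer-local orientation (so a type I-E 5' AAG and
    a Cas9-style 3' NGG are both direct to state). Matches whose PAM
    window is truncated by a sequence end get pam_ok=False with a
    "truncated" note.
    """
    if pam is not None:
        pam_seq, pam_side = pam[0].upper(), pam[1]
        if pam_side not in PAM_SIDES:
            raise ValueError(f"pam side must be one of {sorted(PAM_SIDES)}")
    matches: List[ProtospacerMatch] = []
    for spacer_id, spacer in spacers.items():
        spacer = spacer.upper().replace("U", "T")
        validate_dna(spacer, name=f"spacer {spacer_id!r}")
        if len(spacer) < 20:
            raise ValueError(f"spacer {spacer_id!r} is shorter than 20 nt")
        for seq_id, target in targets.items():
            for probe, strand in ((spacer, "+"), (revcomp(spacer), "-")):
                for start in find_all(target, probe):
                    end = start + len(probe)
                    pam_ok: Optional[bool] = None
                    pam_observed = ""
                    note = ""
                    if pam is not None:
                        plen = len(pam_seq)
                        # PAM window in protospacer orientation
                        if (strand == "+") == (pam_side == "5prime"):
                            window = target[max(0, start - plen) : start]
                        else:
                            window = target[end : end + plen]
                        if strand == "-":
                            window = revcomp(window)
                        pam_observed = window
                        if len(window) < plen:
                            pam_ok = False
                            note = "truncated"
                        else:
                            pam_ok = matches_iupac(window, pam_seq)
                    matches.append(
                        ProtospacerMatch(
                            spacer_id=spacer_id,
                            target_seq_id=seq_id,
                            start=start,
                            end=end,
                            strand=strand,
                            pam_ok=pam_ok,
                            pam_observed=pam_observed,
                            note=note,
                        )
                    )
    return sorted(
        matches, key=lambda m: (m.spacer_id, m.target_seq_id, m.start, m.strand)
    )


def matches_to_rows(matches: List[ProtospacerMatch]) -> List[dict]:
    return [
        {
            "spacer_id": m.spacer_id,
            "target": m.target_seq_id,
            "start_1based": m.start + 1,
            "end_1based": m.end,
            "strand": m.strand,
            "pam_observed": m.pam_observed,
            "pam_ok": m.pam_ok,
            "note": m.note,
        }
        for m in matches
    ]
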