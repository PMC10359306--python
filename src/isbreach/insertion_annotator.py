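"""Mapping TSD-verified insertions onto gene annotations.

Covers four jobs: naming the disrupted gene (maximal-overlap rule),
extracting the genes in a +/- 10 kb context window, collapsing events
into an insertion-spectrum matrix of unique target sites, and
predicting diagnostic PCR amplicon sizes.

The "insertion point" used throughout is the + strand coordinate of the
boundary between the upstream repeat copy and the element, i.e. the
element's start.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

from ._seq import find_all, gc_fraction, revcomp
from .sequence_io import GeneModel, ISElement
from .tsd_caller import TSDCall


@dataclass
class InsertionAnnotation:
    call: TSDCall
    disrupted_gene: Optional[str] = None
    system_label: Optional[str] = None
    relative_position: Optional[float] = None
    position_on_gene: Optional[int] = None
    orientation: Optional[str] = None  # "same" / "opposite" vs gene strand

    @property
    def insertion_point(self) -> int:
        return self.call.hit.start


@dataclass
class SpectrumMatrix:
    """Unique TSD sites (columns) per gene (rows), with inserting families.

    ``sites`` are (gene, position-on-gene, k) keys; ``cells`` maps a
    site to the set of element families that inserted there.
    ``multi_mapping`` flags TSD sequences observed at more than one
    site — candidates for false-positive review.
    """

    genes: List[str] = field(default_factory=list)
    sites: List[Tuple[str, int, int]] = field(default_factory=list)
    cells: Dict[Tuple[str, int, int], frozenset] = field(default_factory=dict)
    site_gc: Dict[Tuple[str, int, int], float] = field(default_factory=dict)
    site_tsd: Dict[Tuple[str, int, int], str] = field(default_factory=dict)
    multi_mapping: List[str] = field(default_factory=list)

    def unique_site_count(self, gene: str) -> int:
        return sum(1 for s in self.sites if s[0] == gene)

    def to_dict(self) -> dict:
        return {
            "genes": self.genes,
            "sites": [list(s) for s in self.sites],
            "cells": {f"{g}:{p}:{k}": sorted(v) for (g, p, k), v in self.cells.items()},
            "site_gc": {f"{g}:{p}:{k}": v for (g, p, k), v in self.site_gc.items()},
            "site_tsd": {f"{g}:{p}:{k}": v for (g, p, k), v in self.site_tsd.items()},
            "multi_mapping": self.multi_mapping,
        }


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def annotate_insertion(call: TSDCall, genes: List[GeneModel]) -> InsertionAnnotation:
    """Assign the disrupted gene by maximal element/CDS overlap.

    Ties break to the leftmost gene start. Intergenic insertions leave
    ``disrupted_gene`` unset. ``relative_position`` is the insertion
    point's fractional position along the gene, measured on the gene's
    own strand.
    """
    hit = call.hit
    same_seq = [g for g in genes if g.seq_id == hit.seq_id]
    if genes and not same_seq:
        raise ValueError(
            f"no annotations on sequence {hit.seq_id!r} "
            f"(annotations cover {sorted({g.seq_id for g in genes})})"
        )
    best: Optional[GeneModel] = None
    best_ov = 0
    for g in sorted(same_seq, key=lambda g: g.start):
        ov = _overlap(hit.start, hit.end, g.start0, g.end0)
        if ov > best_ov:
            best, best_ov = g, ov
    ann = InsertionAnnotation(call=call)
    if best is not None:
        point = hit.start
        if best.strand == "+":
            pos = point - best.start0
        else:
            pos = best.end0 - point
        pos = min(best.length, max(0, pos))
        ann.disrupted_gene = best.gene_name
        ann.system_label = best.system_label
        ann.position_on_gene = pos
        ann.relative_position = pos / best.length
        ann.orientation = "same" if hit.strand == best.strand else "opposite"
    return ann


def scan_context(
    call: TSDCall,
    genes: List[GeneModel],
    window: int = 10_000,
) -> List[GeneModel]:
    """Genes overlapping [element_start - window, element_end + window)."""
    if window < 0:
        raise ValueError("window must be non-negative")
    hit = call.hit
    lo = max(0, hit.start - window)
    hi = min(hit.target_length, hit.end + window)
    return [
        g
        for g in genes
        if g.seq_id == hit.seq_id and _overlap(lo, hi, g.start0, g.end0) > 0
    ]


def build_spectrum(
    annotations: List[InsertionAnnotation],
    families: Optional[Mapping[str, str]] = None,
) -> SpectrumMatrix:
    """Collapse insertion events into unique (gene, position, k) sites.

    ``families`` maps element names to family labels; by default the
    element name stands for its family. Only annotations with a
    disrupted gene and a called TSD contribute sites. TSD sequences seen
    at more than one site are flagged in ``multi_mapping``.
    """
    families = dict(families or {})
    spectrum = SpectrumMatrix()
    raw_cells: Dict[Tuple[str, int, int], set] = {}
    gene_starts: Dict[str, List[int]] = {}
    by_tsd: Dict[str, set] = {}
    gene_order: List[str] = []

    for ann in annotations:
        if ann.disrupted_gene is None or ann.call.k == 0:
            continue
        gene = ann.disrupted_gene
        if gene not in gene_order:
            gene_order.append(gene)
        key = (gene, ann.position_on_gene, ann.call.k)
        fam = families.get(ann.call.hit.element_name, ann.call.hit.element_name)
        raw_cells.setdefault(key, set()).add(fam)
        spectrum.site_gc[key] = gc_fraction(ann.call.tsd_sequence)
        spectrum.site_tsd[key] = ann.call.tsd_sequence
        by_tsd.setdefault(ann.call.tsd_sequence, set()).add(key)

    spectrum.genes = gene_order
    spectrum.sites = sorted(raw_cells)
    spectrum.cells = {k: frozenset(v) for k, v in raw_cells.items()}
    spectrum.multi_mapping = sorted(t for t, keys in by_tsd.items() if len(keys) > 1)
    return spectrum


def predict_amplicons(
    template_sequence: str,
    primer_pair: Tuple[str, str],
    insertions: List[Tuple[ISElement, int]],
) -> List[int]:
    """Diagnostic amplicon sizes for a set of independent insertion events.

    The base amplicon spans the two primer 5' ends inclusive; an
    insertion of an element with duplication length k inside the span
    enlarges the product by element.length + k (the one extra repeat
    copy). Returns ``[base]`` when ``insertions`` is empty, else one
    size per insertion event.
    """
    fwd, rev = (p.upper() for p in primer_pair)
    fwd_sites = list(find_all(template_sequence, fwd))
    if len(fwd_sites) != 1:
        raise ValueError(
            f"forward primer {fwd!r} occurs {len(fwd_sites)} times; need exactly 1"
        )
    rev_probe = revcomp(rev)
    rev_sites = list(find_all(template_sequence, rev_probe))
    if len(rev_sites) != 1:
        raise ValueError(
            f"reverse primer {rev!r} occurs {len(rev_sites)} times; need exactly 1"
        )
    fwd5 = fwd_sites[0]
    rev5 = rev_sites[0] + len(rev_probe) - 1  # 5' end of the reverse primer
    if rev5 <= fwd5:
        raise ValueError("primers are not in amplifying orientation")
    base = rev5 - fwd5 + 1
    if not insertions:
        return [base]
    return [base + element.length + k for element, k in insertions]
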