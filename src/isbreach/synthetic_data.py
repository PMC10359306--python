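"""Ground-truthed synthetic data: annotated loci, element implants, metrics.

The implant operation models transposition the way the downstream
callers expect to see it: a k-mer at the chosen insertion point is
duplicated so that identical copies flank the inserted element, growing
the sequence by exactly element.length + k. All randomness flows from a
single seed; identical seeds give identical outputs.

Coordinate convention: a truth record's ``insertion_point`` is the index
of the first base of the upstream duplication copy, in final (post all
implants) coordinates; the element itself occupies
[insertion_point + k, insertion_point + k + element.length).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._seq import matches_iupac, random_dna, revcomp
from .sequence_io import GeneModel, ISCatalog
from .tsd_caller import TSDCall

_MAX_SITE_DRAWS = 100_000


@dataclass
class ImplantSpec:
    element_name: str
    n_implants: int
    k_distribution: Dict[int, float]
    site_motif: Optional[str] = None
    strand_probability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        total = sum(self.k_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"k_distribution sums to {total}, not 1")
        if not 0.0 <= self.strand_probability <= 1.0:
            raise ValueError("strand_probability must lie in [0, 1]")
        if self.n_implants < 1:
            raise ValueError("n_implants must be positive")


@dataclass
class TruthRecord:
    element_name: str
    seq_id: str
    insertion_point: int  # first base of the upstream TSD copy, final coords
    k: int
    tsd_sequence: str
    strand: str
    disrupted_gene: Optional[str] = None

    @property
    def element_start(self) -> int:
        return self.insertion_point + self.k

    def element_end(self, element_length: int) -> int:
        return self.element_start + element_length


@dataclass
class DetectionMetrics:
    recall: float
    precision: float
    exact_k_rate: float
    n_truth: int
    n_calls: int


def generate_locus(
    n_genes: int,
    gene_length_range: Tuple[int, int],
    intergenic_range: Tuple[int, int],
    gc: float = 0.5,
    seed: int = 0,
    seq_id: str = "locus",
    system_label: Optional[str] = "CRISPR-Cas",
) -> Tuple[str, List[GeneModel]]:
    """A random sequence carrying n non-overlapping CDS features.

    Genes are laid out sequentially with random intergenic gaps, so the
    packing is always feasible; reading-frame validity is not required
    of the synthetic genes. Reproducible by seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be positive")
    for lo, hi in (gene_length_range, intergenic_range):
        if lo <= 0 or hi < lo:
            raise ValueError("ranges must be positive and ordered")
    rng = np.random.default_rng(seed)
    genes: List[GeneModel] = []
    pos = int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
    for i in range(n_genes):
        length = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(
                seq_id=seq_id,
                start=pos + 1,
                end=pos + length,
                strand=strand,
                gene_name=f"{seq_id}_gene_{i + 1}",
                system_label=system_label,
            )
        )
        pos += length + int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
    sequence = random_dna(pos, rng, gc=gc)
    return sequence, genes


def _shift_coords(records: List[TruthRecord], boundary: int, delta: int) -> List[TruthRecord]:
    return [
        replace(r, insertion_point=r.insertion_point + delta)
        if r.insertion_point >= boundary
        else r
        for r in records
    ]


def implant_elements(
    sequence: str,
    genes: Sequence[GeneModel],
    catalog: ISCatalog,
    spec: ImplantSpec,
    seq_id: str = "locus",
    allow_nesting: bool = False,
) -> Tuple[str, List[TruthRecord]]:
    """Insert n copies of one element with duplicated target k-mers.

    Each implant draws k from the spec's length mixture, picks an
    insertion point uniformly (or by rejection sampling against
    ``site_motif``), orients the element by the drawn strand, and
    duplicates the target k-mer around it. Unless ``allow_nesting``,
    points falling inside (or immediately against) a previously
    implanted element are rejected, keeping the truth unambiguous.
    Truth records come out in final coordinates.
    """
    element = catalog.get(spec.element_name)
    if spec.site_motif is not None:
        bad = [k for k in spec.k_distribution if k != len(spec.site_motif)]
        if bad:
            raise ValueError(
                f"k_distribution lengths {bad} disagree with site_motif "
                f"{spec.site_motif!r} of length {len(spec.site_motif)}"
            )
    rng = np.random.default_rng(spec.seed)
    ks = sorted(spec.k_distribution)
    probs = [spec.k_distribution[k] for k in ks]
    seq = sequence
    truths: List[TruthRecord] = []
    # full implant footprints (upstream TSD copy .. downstream TSD copy),
    # maintained in current coordinates
    footprints: List[Tuple[int, int]] = []

    gene_intervals = [(g.start0, g.end0, g.gene_name) for g in genes]

    for _ in range(spec.n_implants):
        k = int(rng.choice(ks, p=probs))
        point = None
        for _attempt in range(_MAX_SITE_DRAWS):
            p = int(rng.integers(0, len(seq) - k + 1))
            kmer = seq[p : p + k]
            if set(kmer) - set("ACGT"):
                continue
            if spec.site_motif is not None and not matches_iupac(kmer, spec.site_motif):
                continue
            # the cut sits at p + k; cutting inside (or against) an earlier
            # footprint would split its element or a TSD copy
            if not allow_nesting and any(
                s - 1 <= p + k <= e + 1 for s, e in footprints
            ):
                continue
            point = p
            break
        if point is None:
            raise ValueError(
                f"no insertion site matching motif {spec.site_motif!r} found in "
                f"{_MAX_SITE_DRAWS} draws; try a looser motif"
            )
        kmer = seq[point : point + k]
        strand = "+" if rng.random() < spec.strand_probability else "-"
        inserted = element.sequence if strand == "+" else revcomp(element.sequence)
        delta = len(inserted) + k
        cut = point + k
        seq = seq[:cut] + inserted + kmer + seq[cut:]
        # shift everything at or beyond the cut downstream by delta
        truths = _shift_coords(truths, cut, delta)
        footprints = [(s + delta, e + delta) if s >= cut else (s, e) for s, e in footprints]
        gene_intervals = [
            (s + delta if s >= cut else s, e + delta if e > cut else e, n)
            for s, e, n in gene_intervals
        ]
        disrupted = next((n for s, e, n in gene_intervals if s <= cut < e), None)
        footprints.append((point, point + k + element.length + k))
        truths.append(
            TruthRecord(
                element_name=element.name,
                seq_id=seq_id,
                insertion_point=point,
                k=k,
                tsd_sequence=kmer,
                strand=strand,
                disrupted_gene=disrupted,
            )
        )
    truths.sort(key=lambda t: t.insertion_point)
    return seq, truths


def evaluate_detection(
    truth: List[TruthRecord],
    calls: List[TSDCall],
    element_lengths: Dict[str, int],
) -> DetectionMetrics:
    """Interval-exact recovery metrics plus the exact-k rate.

    A call recovers a truth record when element name, sequence id and
    element interval all match exactly; the exact-k rate is the fraction
    of recovered records whose called duplication length also equals the
    generated one. (Chance flank extensions can only lengthen k, so the
    exact-k rate isolates that effect from recovery itself.)
    """
    truth_index = {
        (t.element_name, t.seq_id, t.element_start, t.element_end(element_lengths[t.element_name])): t.k
        for t in truth
    }
    recovered = set()
    exact_k = 0
    spurious = 0
    for c in calls:
        key = (c.hit.element_name, c.hit.seq_id, c.hit.start, c.hit.end)
        if key in truth_index:
            if key not in recovered and c.k == truth_index[key]:
                exact_k += 1
            recovered.add(key)
        else:
            spurious += 1
    n_truth = len(truth_index)
    n_calls = len(calls)
    recall = len(recovered) / n_truth if n_truth else 1.0
    precision = (n_calls - spurious) / n_calls if n_calls else 1.0
    exact_rate = exact_k / len(recovered) if recovered else 0.0
    return DetectionMetrics(
        recall=recall,
        precision=precision,
        exact_k_rate=exact_rate,
        n_truth=n_truth,
        n_calls=n_calls,
    )


def truth_to_rows(truth: List[TruthRecord]) -> List[dict]:
    return [
        {
            "element": t.element_name,
            "seq_id": t.seq_id,
            "insertion_point_1based": t.insertion_point + 1,
            "k": t.k,
            "tsd_sequence": t.tsd_sequence,
            "strand": t.strand,
            "disrupted_gene": t.disrupted_gene or "",
        }
        for t in truth
    ]
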