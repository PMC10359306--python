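"""Loading and validation of IS catalogs, target sequences and annotations.

Internal coordinates are 0-based half-open. File I/O speaks the native
conventions of each format: FASTA records are plain strings, GFF3 is
1-based inclusive. :class:`GeneModel` stores the GFF3 coordinates and
exposes ``start0``/``end0`` properties for interval arithmetic.

Catalog sequences must be strict A/C/G/T probes (exact matching depends
on it); target sequences tolerate other letters, which simply never
match downstream.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import gffutils
import pandas as pd
from Bio import SeqIO

from ._seq import DNA_ALPHABET, normalize, validate_dna

PathLike = Union[str, Path]


@dataclass
class ISElement:
    """One catalog element: sequence plus family-level TSD expectations."""

    name: str
    family: str
    sequence: str
    canonical_tsd_lengths: frozenset
    tsd_motif: Optional[str] = None

    def __post_init__(self):
        self.sequence = normalize(self.sequence)
        validate_dna(self.sequence, name=f"catalog record {self.name!r}")
        if len(self.sequence) < 100:
            raise ValueError(
                f"element {self.name!r} is {len(self.sequence)} bp; "
                "catalog elements must be at least 100 bp"
            )
        self.canonical_tsd_lengths = frozenset(int(k) for k in self.canonical_tsd_lengths)
        if not self.canonical_tsd_lengths:
            raise ValueError(f"element {self.name!r} has no canonical TSD lengths")
        for k in self.canonical_tsd_lengths:
            if not 2 <= k <= 30:
                raise ValueError(
                    f"canonical TSD length {k} of element {self.name!r} outside [2, 30]"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ISCatalog:
    """A validated, name-unique collection of ISElements."""

    elements: List[ISElement] = field(default_factory=list)

    def __post_init__(self):
        names = [e.name for e in self.elements]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ValueError(f"duplicate element names in catalog: {sorted(dupes)}")
        for a in self.elements:
            for b in self.elements:
                if a.name != b.name and a.sequence in b.sequence:
                    warnings.warn(
                        f"element {a.name!r} is an exact substring of {b.name!r}; "
                        "hits will be reported for both",
                        stacklevel=2,
                    )

    def __iter__(self):
        return iter(self.elements)

    def __len__(self):
        return len(self.elements)

    def get(self, name: str) -> ISElement:
        for e in self.elements:
            if e.name == name:
                return e
        raise KeyError(name)


@dataclass
class GeneModel:
    """A gene/CDS feature with GFF3 (1-based inclusive) coordinates."""

    seq_id: str
    start: int
    end: int
    strand: str
    gene_name: str
    system_label: Optional[str] = None

    def __post_init__(self):
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"feature {self.gene_name!r}: invalid coordinates "
                f"start={self.start} end={self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ValueError(
                f"feature {self.gene_name!r}: unknown strand {self.strand!r}"
            )

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based half-open end."""
        return self.end

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def load_is_catalog(fasta_source: PathLike, metadata_table: PathLike) -> ISCatalog:
    """Read a catalog FASTA plus its metadata TSV into a validated ISCatalog.

    The TSV dialect is fixed: columns ``name``, ``family``,
    ``canonical_tsd_lengths`` (comma-separated integers) and an optional
    ``tsd_motif``. Every FASTA record must have a metadata row.
    """
    records = list(SeqIO.parse(str(fasta_source), "fasta"))
    if not records:
        raise ValueError("empty catalog: no FASTA records found")

    meta = pd.read_csv(metadata_table, sep="\t", dtype=str)
    required = {"name", "family", "canonical_tsd_lengths"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"catalog metadata missing columns: {sorted(missing)}")
    meta = meta.set_index("name")

    elements = []
    for rec in records:
        if rec.id not in meta.index:
            raise ValueError(f"catalog record {rec.id!r} has no metadata row")
        row = meta.loc[rec.id]
        lengths = frozenset(int(x) for x in str(row["canonical_tsd_lengths"]).split(","))
        motif = row.get("tsd_motif")
        if motif is not None and (pd.isna(motif) or motif == ""):
            motif = None
        elements.append(
            ISElement(
                name=rec.id,
                family=str(row["family"]),
                sequence=str(rec.seq),
                canonical_tsd_lengths=lengths,
                tsd_motif=motif,
            )
        )
    return ISCatalog(elements)


def write_is_catalog(catalog: ISCatalog, fasta_path: PathLike, metadata_path: PathLike) -> None:
    """Write a catalog back to FASTA + metadata TSV (round-trip inverse)."""
    with open(fasta_path, "w") as fh:
        for e in catalog:
            fh.write(f">{e.name}\n{e.sequence}\n")
    rows = [
        {
            "name": e.name,
            "family": e.family,
            "canonical_tsd_lengths": ",".join(str(k) for k in sorted(e.canonical_tsd_lengths)),
            "tsd_motif": e.tsd_motif or "",
        }
        for e in catalog
    ]
    pd.DataFrame(rows).to_csv(metadata_path, sep="\t", index=False)


def load_targets(fasta_source: PathLike) -> Dict[str, str]:
    """Read target sequences; uppercase, U->T, non-ACGT letters tolerated."""
    targets = {}
    for rec in SeqIO.parse(str(fasta_source), "fasta"):
        targets[rec.id] = normalize(str(rec.seq))
    if not targets:
        raise ValueError("no target sequences found")
    return targets


def write_fasta(sequences: Dict[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


_FEATURE_TYPES = {"gene", "CDS"}


def load_annotations(gff3_source: Union[PathLike, str]) -> List[GeneModel]:
    """Parse gene/CDS features from GFF3 into GeneModels.

    Accepts a path or raw GFF3 text. Coordinates are preserved as
    1-based inclusive; the result is sorted by (seq_id, start).
    """
    source = str(gff3_source)
    from_string = "\t" in source or "\n" in source
    if not from_string and not Path(source).exists():
        raise FileNotFoundError(source)
    db = gffutils.create_db(
        source,
        dbfn=":memory:",
        from_string=from_string,
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes = []
    for feat in db.all_features():
        if feat.featuretype not in _FEATURE_TYPES:
            continue
        name = (
            feat.attributes.get("Name", [None])[0]
            or feat.attributes.get("ID", [None])[0]
            or feat.attributes.get("locus_tag", [None])[0]
            or f"{feat.seqid}:{feat.start}-{feat.end}"
        )
        system = feat.attributes.get("system", [None])[0]
        genes.append(
            GeneModel(
                seq_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                gene_name=name,
                system_label=system,
            )
        )
    genes.sort(key=lambda g: (g.seq_id, g.start))
    return genes


def write_annotations(genes: List[GeneModel], path: PathLike, feature_type: str = "CDS") -> None:
    """Write GeneModels as a GFF3 file (inverse of load_annotations)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_name};Name={g.gene_name}"
            if g.system_label:
                attrs += f";system={g.system_label}"
            fh.write(
                f"{g.seq_id}\t.\t{feature_type}\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
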