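"""Shared fixtures: deterministic catalogs, loci and file bundles.

Everything is generated programmatically; no binary fixtures.
"""

from __future__ import annotations

import numpy as np
import pytest

from isbreach import ISCatalog, ISElement
from isbreach._seq import random_dna


def make_element(name: str, family: str, length: int, canonical, seed: int, motif=None) -> ISElement:
    rng = np.random.default_rng(seed)
    return ISElement(
        name=name,
        family=family,
        sequence=random_dna(length, rng),
        canonical_tsd_lengths=frozenset(canonical),
        tsd_motif=motif,
    )


@pytest.fixture(scope="session")
def is1_like() -> ISElement:
    """A 768 bp element with 8/9 bp canonical duplication lengths."""
    return make_element("IS1x", "IS1", 768, {8, 9}, seed=101, motif="NRAWWWWN")


@pytest.fixture(scope="session")
def is10_like() -> ISElement:
    """A 1329 bp element with a 9 bp canonical duplication length."""
    return make_element("IS10x", "IS10", 1329, {9}, seed=102, motif="NRCWNWRYN")


@pytest.fixture(scope="session")
def catalog(is1_like, is10_like) -> ISCatalog:
    return ISCatalog([is1_like, is10_like])


@pytest.fixture
def catalog_files(tmp_path, catalog):
    """Catalog written to disk as (fasta_path, metadata_path)."""
    from isbreach.sequence_io import write_is_catalog

    fasta = tmp_path / "catalog.fasta"
    meta = tmp_path / "catalog.tsv"
    write_is_catalog(catalog, fasta, meta)
    return fasta, meta


def brute_force_hits(element_seq: str, target: str):
    """Independent all-offsets oracle for exact full-length matching."""
    comp = str.maketrans("ACGT", "TGCA")
    rc = element_seq.translate(comp)[::-1]
    L = len(element_seq)
    out = []
    for i in range(len(target) - L + 1):
        window = target[i : i + L]
        if window == element_seq:
            out.append((i, i + L, "+"))
        if window == rc:
            out.append((i, i + L, "-"))
    return sorted(out)


def brute_force_tsd(target: str, start: int, end: int, k_min: int, k_max: int) -> int:
    """Independent largest-duplication oracle: ascending scan, keep the max."""
    best = 0
    for k in range(k_min, k_max + 1):
        if start - k < 0 or end + k > len(target):
            continue
        up = target[start - k : start]
        if up == target[end : end + k] and set(up) <= set("ACGT"):
            best = k
    return best
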