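"""Position-frequency matrices, IUPAC consensus and TSD summary statistics.

PFMs carry plain per-position frequencies with no pseudocounts; motif
similarity is the Pearson correlation of two PFMs flattened to
4k-vectors. Both choices are deliberate defaults, not the only
reasonable reading, and are therefore confined to this module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from ._seq import SETS_TO_IUPAC, gc_fraction, validate_dna

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class PFM:
    """Per-position nucleotide frequencies over n equal-length sequences.

    ``freq`` has shape (4, k) with rows in A, C, G, T order; every
    column sums to 1 within 1e-12.
    """

    k: int
    freq: np.ndarray
    n: int

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (4, self.k):
            raise ValueError(f"freq must be 4x{self.k}, got {self.freq.shape}")
        if self.n < 1:
            raise ValueError("a PFM needs at least one contributing sequence")
        if np.any(self.freq < 0) or np.any(self.freq > 1):
            raise ValueError("frequencies must lie in [0, 1]")
        colsums = self.freq.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-12):
            raise ValueError("PFM columns must each sum to 1")

    def to_jaspar(self, name: str = "PFM") -> str:
        lines = [f">{name}"]
        for i, b in enumerate(BASES):
            vals = "\t".join(f"{v:.6f}" for v in self.freq[i])
            lines.append(f"{b}\t[\t{vals}\t]")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {"k": self.k, "n": self.n, "freq": {b: self.freq[i].tolist() for i, b in enumerate(BASES)}}


@dataclass
class TSDSummary:
    length_proportions: Dict[int, float]
    gc_values: List[float]
    group_comparison: Optional[Tuple[float, float]] = None  # (t, two-sided p)


def build_pfm(tsds: Sequence[str]) -> PFM:
    """Count-based PFM of equal-length ACGT strings, no pseudocounts."""
    if not tsds:
        raise ValueError("cannot build a PFM from zero sequences")
    lengths = {len(t) for t in tsds}
    if len(lengths) != 1:
        raise ValueError(
            f"mixed TSD lengths {sorted(lengths)}: pre-cluster the input by "
            "element type and TSD length before building a PFM"
        )
    k = lengths.pop()
    counts = np.zeros((4, k), dtype=float)
    for t in tsds:
        t = t.upper()
        validate_dna(t, name="TSD")
        for i, base in enumerate(t):
            counts[_BASE_INDEX[base], i] += 1
    return PFM(k=k, freq=counts / len(tsds), n=len(tsds))


def pfm_pearson(a: PFM, b: PFM) -> float:
    """Pearson correlation of two PFMs flattened to 4k frequency vectors."""
    if a.k != b.k:
        raise ValueError(
            f"PFMs of different lengths ({a.k} vs {b.k}) are not comparable; "
            "motifs correlate only within a length class"
        )
    x = a.freq.ravel()
    y = b.freq.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: a uniform PFM has undefined correlation")
    if np.array_equal(x, y):
        return 1.0
    r, _ = stats.pearsonr(x, y)
    return float(r)


_TWO_BASE_CODES = {
    tuple(sorted(pair)): code
    for code, pair in [("R", "AG"), ("Y", "CT"), ("S", "CG"), ("W", "AT"), ("K", "GT"), ("M", "AC")]
}


def consensus_iupac(pfm: PFM, major: float = 0.75, pair: float = 0.9) -> str:
    """Reduce a PFM to an IUPAC string.

    Per column: the single base whose frequency reaches ``major``;
    otherwise the two-base degenerate code when the top two frequencies
    sum to at least ``pair``; otherwise N.
    """
    for t in (major, pair):
        if not 0.5 < t <= 1.0:
            raise ValueError("thresholds must lie in (0.5, 1]")
    out = []
    for col in pfm.freq.T:
        order = np.argsort(col)[::-1]
        if col[order[0]] >= major:
            out.append(BASES[order[0]])
        elif col[order[0]] + col[order[1]] >= pair:
            top2 = tuple(sorted(BASES[i] for i in order[:2]))
            out.append(_TWO_BASE_CODES[top2])
        else:
            out.append("N")
    return "".join(out)


def tsd_summary(
    tsds: Sequence[str],
    groups: Optional[Tuple[Sequence[str], Sequence[str]]] = None,
    equal_var: bool = False,
) -> TSDSummary:
    """Length-mixture proportions, per-TSD GC, optional two-group t-test.

    ``groups`` is a 2-way split of TSD sequences whose GC distributions
    are compared with a two-sided two-sample t-test (Welch by default;
    ``equal_var=True`` selects the pooled form). Groups with fewer than
    two members skip the comparison with a warning.
    """
    if not tsds:
        raise ValueError("no TSDs supplied")
    lengths = [len(t) for t in tsds]
    props = {k: lengths.count(k) / len(lengths) for k in sorted(set(lengths))}
    gcs = [gc_fraction(t) for t in tsds]
    comparison = None
    if groups is not None:
        g1, g2 = ([gc_fraction(t) for t in g] for g in groups)
        if len(g1) < 2 or len(g2) < 2:
            warnings.warn("a group has fewer than 2 TSDs; t comparison omitted")
        else:
            t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
            comparison = (float(t), float(p))
    return TSDSummary(length_proportions=props, gc_values=gcs, group_comparison=comparison)
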