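"""Synonymous recoding of coding sequences against motifs and repeats.

Given a CDS, a set of IUPAC target-site motifs and a minimum repeat
length, the recoder applies greedy left-to-right passes of seeded
synonymous codon substitutions until no window matches any motif and no
exact substring of the minimum length occurs twice. Translation and
length are preserved by construction; the start and stop codons are
never touched.

A window the greedy step cannot fix is re-checked by exhaustive
enumeration of every synonymous codon combination overlapping it; only
a provably unfixable window is reported as a residual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio.Data import CodonTable

from ._seq import iupac_regex, revcomp

Interval = Tuple[int, int]


@dataclass
class RecodeSpec:
    """Configuration of one recoding run."""

    motifs: List[str]
    min_repeat: int = 10
    codon_table: Union[str, int] = "Standard"
    max_passes: int = 10
    seed: int = 0
    motif_both_strands: bool = False
    repeat_revcomp: bool = False

    def __post_init__(self):
        if not self.motifs:
            raise ValueError("at least one motif is required")
        if self.min_repeat < 4:
            raise ValueError("min_repeat must be >= 4")
        for m in self.motifs:
            iupac_regex(m)  # validates the alphabet
        _get_codon_table(self.codon_table)  # validates the table id


@dataclass
class RecodeResult:
    sequence: str
    changed_codons: List[int] = field(default_factory=list)
    residual_motif_sites: List[Tuple[int, int, str]] = field(default_factory=list)
    residual_repeats: List[Tuple[int, int, str]] = field(default_factory=list)

    @property
    def clean(self) -> bool:
        return not self.residual_motif_sites and not self.residual_repeats


def _get_codon_table(table: Union[str, int]) -> CodonTable.CodonTable:
    if isinstance(table, int):
        return CodonTable.unambiguous_dna_by_id[table]
    return CodonTable.unambiguous_dna_by_name[table]


def _codon_maps(table: Union[str, int]) -> Tuple[Dict[str, str], Dict[str, List[str]]]:
    ct = _get_codon_table(table)
    codon_to_aa = dict(ct.forward_table)
    for stop in ct.stop_codons:
        codon_to_aa[stop] = "*"
    aa_to_codons: Dict[str, List[str]] = {}
    for codon, aa in codon_to_aa.items():
        aa_to_codons.setdefault(aa, []).append(codon)
    return codon_to_aa, aa_to_codons


def find_motif_sites(
    sequence: str,
    iupac_pattern: str,
    both_strands: bool = False,
) -> List[Interval]:
    """Every 0-based half-open window satisfying the pattern positionwise.

    With ``both_strands``, windows whose reverse complement satisfies
    the pattern are also reported (still in forward coordinates); this
    is equivalent to matching the reverse-complemented pattern forward.
    """
    sequence = sequence.upper()
    k = len(iupac_pattern)
    sites = {(m.start(), m.start() + k) for m in iupac_regex(iupac_pattern).finditer(sequence)}
    if both_strands:
        rc_pattern = revcomp(iupac_pattern.upper())
        sites |= {(m.start(), m.start() + k) for m in iupac_regex(rc_pattern).finditer(sequence)}
    return sorted(sites)


def find_repeat_windows(
    sequence: str,
    min_repeat: int,
    include_revcomp: bool = False,
) -> List[Interval]:
    """Windows of length min_repeat whose substring occurs more than once.

    Any exact repeat of length >= min_repeat contains a duplicated
    min_repeat-mer, so eliminating these windows eliminates all longer
    repeats as well. With ``include_revcomp`` a window is also offending
    when its reverse complement occurs elsewhere.
    """
    k = min_repeat
    occurrences: Dict[str, List[int]] = {}
    for i in range(len(sequence) - k + 1):
        occurrences.setdefault(sequence[i : i + k], []).append(i)
    windows = []
    for kmer, locs in occurrences.items():
        offending = len(locs) > 1
        if not offending and include_revcomp:
            rc = revcomp(kmer)
            rc_locs = occurrences.get(rc, [])
            # a self-revcomp k-mer at a single locus is not a repeat
            offending = bool(rc_locs) and (rc != kmer or len(rc_locs) > 1)
        if offending:
            windows.extend((i, i + k) for i in locs)
    return sorted(windows)


def _offending_windows(seq: str, spec: RecodeSpec) -> Tuple[List[Tuple[Interval, str]], int]:
    """All offending windows plus a scalar offence count for greedy scoring."""
    out: List[Tuple[Interval, str]] = []
    for motif in spec.motifs:
        for iv in find_motif_sites(seq, motif, spec.motif_both_strands):
            out.append((iv, f"motif:{motif}"))
    for iv in find_repeat_windows(seq, spec.min_repeat, spec.repeat_revcomp):
        out.append((iv, "repeat"))
    out.sort()
    return out, len(out)


def _window_codons(iv: Interval, n_codons: int) -> List[int]:
    """Indices of mutable codons overlapping a window (start/stop excluded)."""
    first = iv[0] // 3
    last = (iv[1] - 1) // 3
    return [c for c in range(first, last + 1) if 0 < c < n_codons - 1]


def _synonyms(codon: str, codon_to_aa, aa_to_codons) -> List[str]:
    return [c for c in aa_to_codons[codon_to_aa[codon]] if c != codon]


def recode_cds(cds: str, spec: RecodeSpec) -> RecodeResult:
    """Eliminate motif matches and exact repeats by synonymous substitution.

    Greedy passes walk the offending windows left to right; for each
    window, single-codon synonymous substitutions are tried first
    (fewest base changes first, seeded random order within ties), then
    exhaustive combinations over the window's codons. A substitution is
    accepted only if it strictly lowers the global offence count. After
    ``spec.max_passes`` (or when no substitution helps) the remaining
    windows are reported as residuals; each residual has been proven
    locally unavoidable by the exhaustive stage.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    codon_to_aa, aa_to_codons = _codon_maps(spec.codon_table)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for idx, codon in enumerate(codons[:-1]):
        if codon_to_aa.get(codon) == "*":
            raise ValueError(f"internal stop codon {codon} at codon {idx + 1}")
        if codon not in codon_to_aa:
            raise ValueError(f"unknown codon {codon!r} at codon {idx + 1}")

    rng = np.random.default_rng(spec.seed)
    seq = cds
    changed: set = set()

    def try_substitution(candidate_codons: Sequence[Tuple[int, str]], current_count: int) -> Optional[str]:
        """Apply a multi-codon substitution; return new seq if it helps."""
        trial = list(seq)
        for ci, newc in candidate_codons:
            trial[3 * ci : 3 * ci + 3] = newc
        trial_seq = "".join(trial)
        _, count = _offending_windows(trial_seq, spec)
        return trial_seq if count < current_count else None

    for _ in range(spec.max_passes):
        windows, count = _offending_windows(seq, spec)
        if count == 0:
            break
        progressed = False
        for iv, _kind in windows:
            # the sequence may have changed since the list was computed
            cur_windows, cur_count = _offending_windows(seq, spec)
            if (iv, _kind) not in cur_windows:
                continue
            mutable = _window_codons(iv, len(codons))
            fixed = None
            # stage 1: single-codon substitutions, fewest base changes first
            singles = []
            for ci in mutable:
                codon = seq[3 * ci : 3 * ci + 3]
                for alt in _synonyms(codon, codon_to_aa, aa_to_codons):
                    dist = sum(a != b for a, b in zip(codon, alt))
                    singles.append((dist, rng.random(), ci, alt))
            for _dist, _jitter, ci, alt in sorted(singles):
                fixed = try_substitution([(ci, alt)], cur_count)
                if fixed is not None:
                    changed.add(ci)
                    break
            # stage 2: exhaustive combos over the window's codons
            if fixed is None and len(mutable) > 1:
                option_lists = []
                for ci in mutable:
                    codon = seq[3 * ci : 3 * ci + 3]
                    option_lists.append([(ci, c) for c in [codon] + _synonyms(codon, codon_to_aa, aa_to_codons)])
                n_combos = 1
                for ol in option_lists:
                    n_combos *= len(ol)
                if n_combos <= 20000:
                    for combo in itertools.product(*option_lists):
                        subs = [(ci, c) for ci, c in combo if c != seq[3 * ci : 3 * ci + 3]]
                        if not subs:
                            continue
                        fixed = try_substitution(subs, cur_count)
                        if fixed is not None:
                            changed.update(ci for ci, _ in subs)
                            break
            if fixed is not None:
                seq = fixed
                progressed = True
        if not progressed:
            break

    residual_windows, _ = _offending_windows(seq, spec)
    result = RecodeResult(sequence=seq, changed_codons=sorted(changed))
    for iv, kind in residual_windows:
        entry = (iv[0], iv[1], kind)
        if kind.startswith("motif:"):
            result.residual_motif_sites.append(entry)
        else:
            result.residual_repeats.append(entry)
    return result


def is_residual_unavoidable(seq: str, iv: Interval, spec: RecodeSpec) -> bool:
    """Exhaustively verify that no synonymous combination over the window's
    codons lowers the global offence count (start/stop codons immutable)."""
    codon_to_aa, aa_to_codons = _codon_maps(spec.codon_table)
    n_codons = len(seq) // 3
    mutable = _window_codons(iv, n_codons)
    _, base_count = _offending_windows(seq, spec)
    option_lists = []
    for ci in mutable:
        codon = seq[3 * ci : 3 * ci + 3]
        option_lists.append([codon] + _synonyms(codon, codon_to_aa, aa_to_codons))
    for combo in itertools.product(*option_lists) if option_lists else []:
        trial = list(seq)
        for ci, newc in zip(mutable, combo):
            trial[3 * ci : 3 * ci + 3] = newc
        _, count = _offending_windows("".join(trial), spec)
        if count < base_count:
            return False
    return True


def translate(cds: str, table: Union[str, int] = "Standard") -> str:
    """Translate a CDS (stop rendered as '*')."""
    codon_to_aa, _ = _codon_maps(table)
    cds = cds.upper().replace("U", "T")
    return "".join(codon_to_aa[cds[i : i + 3]] for i in range(0, len(cds), 3))
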