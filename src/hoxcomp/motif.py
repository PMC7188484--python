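"""Mismatch-tolerant IUPAC motif scanning on both strands.

The scanner reports every window of pattern length whose Hamming distance to
the pattern — counting a position as a mismatch only when the observed base
lies outside the IUPAC set at that position — is within the pattern's
mismatch budget.  A target base N matches nothing under the default policy
(conservative: masked/ambiguous target positions never support a hit); a
flag lets N match pattern N only.

Minus-strand hits are found by scanning the plus strand with the
reverse-complemented pattern: for any window ``w``,
``mismatches(P, revcomp(w)) == mismatches(revcomp(P), w)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .seqio import GenomicSequence

# IUPAC nucleotide codes -> the set of concrete bases each matches
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

NPolicy = Literal["never", "n-matches-n"]


class MotifError(ValueError):
    pass


def revcomp(residues: str) -> str:
    """Reverse complement over {A,C,G,T,N} (N maps to N).

    Also accepts degenerate IUPAC codes, complementing their sets, so that
    patterns can be reverse-complemented for minus-strand scanning.
    """
    bad = set(residues) - set(IUPAC_SETS)
    if bad:
        raise MotifError(f"disallowed characters in sequence: {sorted(bad)}")
    return residues.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifPattern:
    """An IUPAC search pattern with a mismatch budget."""

    name: str
    iupac: str
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not self.iupac:
            raise MotifError("empty pattern")
        bad = set(self.iupac) - set(IUPAC_SETS)
        if bad:
            raise MotifError(f"pattern {self.name!r}: invalid IUPAC codes {sorted(bad)}")
        if not 0 <= self.max_mismatch < len(self.iupac):
            raise MotifError(
                f"pattern {self.name!r}: max_mismatch must be in [0, {len(self.iupac)})"
            )

    def __len__(self) -> int:
        return len(self.iupac)


# the patterns used throughout the enhancer-conservation analysis
EO053_MOTIF = MotifPattern("EO053", "ATCATTAATCAT", max_mismatch=1)
ATTAAT_LEFT = MotifPattern("ATTAAT_left", "ATCATTAAT", max_mismatch=0)
ATTAAT_RIGHT = MotifPattern("ATTAAT_right", "ATTAATCAT", max_mismatch=0)
YPWM_CODON_MOTIF = MotifPattern("YPWM", "TAYCCNTGGATG", max_mismatch=0)


@dataclass(frozen=True)
class MotifHit:
    """A located motif occurrence.

    ``site`` holds the plus-strand residues of the interval; for a minus-
    strand hit the pattern matches ``revcomp(site)``.
    """

    seq_id: str
    pattern_name: str
    start: int
    end: int
    strand: str
    site: str
    n_mismatch: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def mismatch_count(pattern: str, word: str, n_policy: NPolicy = "never") -> int:
    """Count positions of *word* outside the IUPAC set of *pattern*.

    A target N counts as a mismatch at every pattern position under the
    default policy; with ``n_policy="n-matches-n"`` it matches pattern N only.
    """
    if len(pattern) != len(word):
        raise MotifError(f"length mismatch: pattern {len(pattern)} vs word {len(word)}")
    n = 0
    for p, b in zip(pattern, word):
        if b == "N":
            if not (n_policy == "n-matches-n" and p == "N"):
                n += 1
        elif b not in IUPAC_SETS[p]:
            n += 1
    return n


def _allowed_matrix(pattern: str, n_policy: NPolicy) -> np.ndarray:
    """(len(pattern), 5) boolean: does target base {A,C,G,T,N} match position j."""
    allowed = np.zeros((len(pattern), 5), dtype=bool)
    for j, code in enumerate(pattern):
        for base in IUPAC_SETS[code]:
            allowed[j, _BASE_INDEX[base]] = True
        if n_policy == "n-matches-n" and code == "N":
            allowed[j, _BASE_INDEX["N"]] = True
    return allowed


def _encode(residues: str) -> np.ndarray:
    codes = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        lut[ord(base)] = idx
    return lut[codes]


def _window_mismatches(codes: np.ndarray, pattern: str, n_policy: NPolicy) -> np.ndarray:
    """Mismatch count of every plus-strand window against *pattern*."""
    k = len(pattern)
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int32)
    allowed = _allowed_matrix(pattern, n_policy)
    mism = np.zeros(n_win, dtype=np.int32)
    for j in range(k):
        mism += ~allowed[j][codes[j:j + n_win]]
    return mism


def scan_sequence(
    seq: GenomicSequence,
    pattern: MotifPattern,
    strands: Iterable[str] = ("+", "-"),
    n_policy: NPolicy = "never",
    dedup_footprint: bool = False,
) -> list[MotifHit]:
    """Report every window within the mismatch budget on the requested strands.

    Hits are sorted by start, then strand ('+' first).  Overlapping hits and
    double-strand hits on the same footprint (near-palindromes) are all
    reported unless ``dedup_footprint`` keeps, per (start, end), the
    lower-mismatch hit (ties broken toward '+').
    """
    strands = tuple(strands)
    if not strands or set(strands) - {"+", "-"}:
        raise MotifError(f"invalid strand selection {strands!r}")
    codes = _encode(seq.residues)
    k = len(pattern)
    hits: list[MotifHit] = []
    for strand in ("+", "-"):
        if strand not in strands:
            continue
        pat = pattern.iupac if strand == "+" else revcomp(pattern.iupac)
        mism = _window_mismatches(codes, pat, n_policy)
        for start in np.nonzero(mism <= pattern.max_mismatch)[0]:
            start = int(start)
            hits.append(MotifHit(
                seq_id=seq.id, pattern_name=pattern.name,
                start=start, end=start + k, strand=strand,
                site=seq.residues[start:start + k], n_mismatch=int(mism[start]),
            ))
    hits.sort(key=lambda h: (h.start, h.strand))
    if dedup_footprint:
        best: dict[tuple[int, int], MotifHit] = {}
        for h in hits:
            cur = best.get(h.interval)
            if cur is None or (h.n_mismatch, h.strand) < (cur.n_mismatch, cur.strand):
                best[h.interval] = h
        hits = sorted(best.values(), key=lambda h: (h.start, h.strand))
    return hits


def scan_many(
    seqs: Sequence[GenomicSequence],
    patterns: Sequence[MotifPattern],
    strands: Iterable[str] = ("+", "-"),
    n_policy: NPolicy = "never",
    dedup_footprint: bool = False,
) -> list[MotifHit]:
    """Scan every sequence with every pattern; concatenated per-sequence hits."""
    out: list[MotifHit] = []
    for seq in seqs:
        for pattern in patterns:
            out.extend(scan_sequence(seq, pattern, strands, n_policy, dedup_footprint))
    return out
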