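"""Random k-mer background control and its analytic i.i.d. counterpart.

The empirical control draws random k-mers, scans them against target
sequence with the same mismatch budget as the focal motif, and summarises
hit density as "one instance every X bp".  The analytic counterpart gives
the exact per-position hit probability for an i.i.d. background: the total
probability mass of the pattern's Hamming ball (all concrete words within
the mismatch budget), summed over the requested strands.

The spacing denominator is single-strand bp scanned even when both strands
are searched, so "one every X bp" is per genomic bp; ``per_strand=True``
doubles the denominator instead.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .motif import IUPAC_SETS, MotifError, MotifPattern, revcomp, scan_many
from .seqio import GenomicSequence

_BASES = "ACGT"


@dataclass(frozen=True)
class DensityResult:
    """Motif-hit density over a scanned sequence set."""

    n_patterns: int
    total_scanned_bp: int           # sum of single-strand sequence lengths
    total_hits: int
    mean_spacing_bp: float | None   # None when there are no hits
    per_pattern_hits: dict[str, int] = field(default_factory=dict)

    @property
    def per_bp_density(self) -> float:
        return self.total_hits / self.total_scanned_bp if self.total_scanned_bp else 0.0


def _validate_probs(base_probs: Sequence[float]) -> np.ndarray:
    probs = np.asarray(base_probs, dtype=float)
    if probs.shape != (4,) or np.any(probs < 0) or not np.isclose(probs.sum(), 1.0):
        raise ValueError(f"base_probs must be a probability 4-vector over ACGT, got {base_probs!r}")
    return probs


def random_kmers(
    k: int,
    n: int,
    seed: int | np.random.Generator,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> list[str]:
    """Draw *n* i.i.d. random k-mers over ACGT (duplicates permitted)."""
    if k < 1 or n < 1:
        raise ValueError("k and n must be >= 1")
    probs = _validate_probs(base_probs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.choice(4, size=(n, k), p=probs)
    return ["".join(_BASES[i] for i in row) for row in draws]


def random_sequence(
    length: int,
    seed: int | np.random.Generator,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
) -> str:
    """An i.i.d. random DNA sequence, for background simulation."""
    probs = _validate_probs(base_probs)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=probs))


def empirical_density(
    seqs: Sequence[GenomicSequence],
    patterns: Sequence[MotifPattern],
    strands: Iterable[str] = ("+", "-"),
    per_strand: bool = False,
    dedup_footprint: bool = False,
) -> DensityResult:
    """Observed hit density of *patterns* over *seqs*.

    ``mean_spacing_bp`` is total scanned bp divided by total hits; a hit-free
    scan yields ``None`` rather than an error.
    """
    if not seqs or not patterns:
        raise ValueError("need at least one sequence and one pattern")
    strands = tuple(strands)
    hits = scan_many(seqs, patterns, strands, dedup_footprint=dedup_footprint)
    per_pattern: dict[str, int] = {p.name: 0 for p in patterns}
    for h in hits:
        per_pattern[h.pattern_name] += 1
    scanned = sum(s.length for s in seqs)
    if per_strand:
        scanned *= len(set(strands))
    total = len(hits)
    return DensityResult(
        n_patterns=len(patterns),
        total_scanned_bp=scanned,
        total_hits=total,
        mean_spacing_bp=scanned / total if total else None,
        per_pattern_hits=per_pattern,
    )


def _strand_match_prob(pattern: str, max_mismatch: int, probs: np.ndarray) -> float:
    """P(random i.i.d. word within *max_mismatch* of *pattern*), one strand.

    Exact dynamic programme over positions on the number of mismatches
    accumulated so far; equivalent to summing per-position base probabilities
    over every word in the Hamming ball.
    """
    # dp[m] = P(m mismatches in the first j positions)
    dp = np.zeros(max_mismatch + 2)
    dp[0] = 1.0
    for code in pattern:
        p_match = sum(probs[_BASES.index(b)] for b in IUPAC_SETS[code])
        new = np.zeros_like(dp)
        new[: max_mismatch + 1] += dp[: max_mismatch + 1] * p_match
        new[1: max_mismatch + 2] += dp[: max_mismatch + 1] * (1.0 - p_match)
        new[max_mismatch + 1] += dp[max_mismatch + 1]  # overflow bucket
        dp = new
    return float(dp[: max_mismatch + 1].sum())


def hamming_ball(pattern: str, max_mismatch: int) -> set[str]:
    """All concrete ACGT words within *max_mismatch* of an IUPAC *pattern*.

    Enumerated by choosing mismatch positions and off-set bases; intended for
    small k / small budgets (tests, near-palindrome union correction).
    """
    k = len(pattern)
    in_sets = [IUPAC_SETS[c] & set(_BASES) for c in pattern]
    out_sets = [set(_BASES) - s for s in in_sets]
    ball: set[str] = set()
    for m in range(max_mismatch + 1):
        for positions in itertools.combinations(range(k), m):
            pos_set = set(positions)
            choices = [sorted(out_sets[j]) if j in pos_set else sorted(in_sets[j])
                       for j in range(k)]
            if any(not c for c in choices):
                continue
            for word in itertools.product(*choices):
                ball.add("".join(word))
    return ball


def expected_density_iid(
    pattern: MotifPattern,
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    strands: Iterable[str] = ("+", "-"),
    dedup_union: bool = False,
) -> float:
    """Exact per-position expected hit density under an i.i.d. background.

    Per strand, this is the probability that a random word falls in the
    pattern's Hamming ball (revcomp'd ball for the minus strand); strand
    contributions are summed.  ``dedup_union`` instead takes the probability
    of the union of the two balls — the footprint-deduplicated density,
    which differs only for (near-)palindromic patterns.
    """
    probs = _validate_probs(base_probs)
    strands = tuple(strands)
    if not strands or set(strands) - {"+", "-"}:
        raise ValueError(f"invalid strand selection {strands!r}")
    if dedup_union and set(strands) == {"+", "-"}:
        fwd = hamming_ball(pattern.iupac, pattern.max_mismatch)
        rev = {revcomp(w) for w in fwd}
        return float(sum(
            np.prod([probs[_BASES.index(b)] for b in word]) for word in fwd | rev
        ))
    density = 0.0
    for strand in strands:
        pat = pattern.iupac if strand == "+" else revcomp(pattern.iupac)
        density += _strand_match_prob(pat, pattern.max_mismatch, probs)
    return density
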