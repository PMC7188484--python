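"""Maximal identical sequence blocks shared by every input sequence.

This is the computation behind multi-species conservation diagrams that
connect "identical sequence blocks present in all species" with vertical
lines, marking inverted occurrences in red.  Identity is exact: no gaps, no
mismatches, and N never matches anything (so blocks never span N).

Definitions
-----------
A *candidate* is an N-free DNA string of length >= ``min_len`` that occurs
in every input sequence, in forward orientation or (when inversions are
allowed) as its reverse complement.  A candidate is reported as a block
unless a single longer candidate covers every one of its occurrences —
i.e. each occurrence interval, in every sequence, lies inside an occurrence
interval of that longer candidate.  Blocks strictly interior to a longer
block at all of their placements are thereby suppressed, while a shorter
string with an extra standalone placement survives as its own block.

Every candidate occurs in the first (reference) sequence, so every
candidate is a substring of some longest shared extension starting at a
reference position; the finder enumerates those extensions incrementally
and takes their substrings as the candidate pool.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .motif import revcomp
from .seqio import GenomicSequence

MAX_PLACEMENTS_PER_SEQ = 10


@dataclass(frozen=True)
class Placement:
    seq_id: str
    start: int
    orientation: str  # 'forward' | 'inverted'

    @property
    def inverted(self) -> bool:
        return self.orientation == "inverted"


@dataclass(frozen=True)
class ConservedBlock:
    """An identical block present in every input sequence.

    ``block_seq`` is given in reference orientation (forward in the first
    input sequence); inverted placements carry its reverse complement on
    their plus strand.
    """

    block_seq: str
    placements: dict[str, tuple[Placement, ...]] = field(hash=False)

    @property
    def length(self) -> int:
        return len(self.block_seq)

    def reference_start(self, ref_id: str) -> int:
        return min(p.start for p in self.placements[ref_id])


def _find_all(text: str, sub: str) -> list[int]:
    """All (overlapping) occurrence starts of *sub* in *text*."""
    out, i = [], text.find(sub)
    while i != -1:
        out.append(i)
        i = text.find(sub, i + 1)
    return out


def _occurrences(word: str, texts: dict[str, str],
                 allow_inversion: bool) -> dict[str, list[Placement]]:
    rc = revcomp(word)
    out: dict[str, list[Placement]] = {}
    for sid, text in texts.items():
        placements = [Placement(sid, i, "forward") for i in _find_all(text, word)]
        if allow_inversion and rc != word:
            placements += [Placement(sid, i, "inverted") for i in _find_all(text, rc)]
        out[sid] = sorted(placements, key=lambda p: (p.start, p.orientation))
    return out


def _present_in_all(word: str, texts: dict[str, str], rcs: dict[str, str],
                    allow_inversion: bool) -> bool:
    for sid, text in texts.items():
        if word in text or (allow_inversion and word in rcs[sid]):
            continue
        return False
    return True


def _shared_extensions(ref: str, texts: dict[str, str], rcs: dict[str, str],
                       min_len: int, allow_inversion: bool) -> set[str]:
    """Longest N-free shared extension at each reference position.

    ``L(i)`` = largest L with ``ref[i:i+L]`` N-free and present in all
    sequences; since any substring of a shared string is shared,
    ``L(i+1) >= L(i) - 1`` and the scan is incremental.  Returns the distinct
    extension strings of length >= min_len (these cover all candidates).
    """
    n = len(ref)
    out: set[str] = set()
    L = 0
    for i in range(n):
        if L > 0:
            L -= 1  # ref[i:i+L] inherited from the previous position
        while (i + L < n and ref[i + L] != "N"
               and _present_in_all(ref[i:i + L + 1], texts, rcs, allow_inversion)):
            L += 1
        if L >= min_len:
            out.add(ref[i:i + L])
    return out


def _covered(inner: dict[str, list[Placement]], outer: dict[str, list[Placement]],
             inner_len: int, outer_len: int) -> bool:
    """Does every inner occurrence lie within some outer occurrence?"""
    for sid, places in inner.items():
        outs = outer.get(sid, [])
        for p in places:
            if not any(o.start <= p.start and p.start + inner_len <= o.start + outer_len
                       for o in outs):
                return False
    return True


def shared_identical_blocks(
    seqs: list[GenomicSequence],
    min_len: int,
    allow_inversion: bool = True,
    max_placements: int = MAX_PLACEMENTS_PER_SEQ,
) -> list[ConservedBlock]:
    """Find every maximal identical block present in all input sequences.

    Blocks are keyed by ``block_seq`` (reference orientation) and sorted by
    their leftmost start in the first input sequence.  Placements are
    enumerated per sequence, capped at *max_placements* with a warning.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences to find shared blocks")
    if min_len < 4:
        raise ValueError("min_len must be >= 4")
    texts = {s.id: s.residues for s in seqs}
    if len(texts) != len(seqs):
        raise ValueError("duplicate sequence ids")
    rcs = {sid: revcomp(t) for sid, t in texts.items()}
    ref_id = seqs[0].id
    ref = texts[ref_id]

    extensions = _shared_extensions(ref, texts, rcs, min_len, allow_inversion)

    candidates: set[str] = set()
    for w in extensions:
        for length in range(min_len, len(w) + 1):
            for j in range(len(w) - length + 1):
                candidates.add(w[j:j + length])

    # collect occurrences, merging a candidate with its reverse complement
    # (same block seen in both orientations) when inversions are allowed
    occ: dict[str, dict[str, list[Placement]]] = {}
    seen_keys: set[str] = set()
    for word in sorted(candidates):
        key = min(word, revcomp(word)) if allow_inversion else word
        if key in seen_keys:
            continue
        if not _present_in_all(word, texts, rcs, allow_inversion):
            continue  # substring taken across nothing shared — cannot happen,
            # but kept as a guard for N-adjacent slices
        seen_keys.add(key)
        # reference orientation: the variant with the leftmost forward
        # occurrence in the reference sequence
        if allow_inversion and revcomp(word) != word:
            s_fwd, s_rev = ref.find(word), ref.find(revcomp(word))
            if s_rev != -1 and (s_fwd == -1 or s_rev < s_fwd):
                word = revcomp(word)
        occ[word] = _occurrences(word, texts, allow_inversion)

    # prune: a candidate dies iff a single longer candidate covers all its
    # occurrences (coverage is transitive, so checking kept blocks suffices)
    kept: list[str] = []
    for word in sorted(occ, key=len, reverse=True):
        if not any(len(other) > len(word)
                   and _covered(occ[word], occ[other], len(word), len(other))
                   for other in kept):
            kept.append(word)

    blocks: list[ConservedBlock] = []
    for word in kept:
        placements: dict[str, tuple[Placement, ...]] = {}
        for sid, places in occ[word].items():
            if len(places) > max_placements:
                warnings.warn(
                    f"block {word[:12]}... has {len(places)} placements in {sid}; "
                    f"capping at {max_placements}",
                    stacklevel=2,
                )
                places = places[:max_placements]
            placements[sid] = tuple(places)
        blocks.append(ConservedBlock(block_seq=word, placements=placements))
    blocks.sort(key=lambda b: (b.reference_start(ref_id), -b.length, b.block_seq))
    return blocks


def blocks_to_connectors(
    blocks: list[ConservedBlock],
    species_order: list[str],
) -> list[dict]:
    """One connector row per block per adjacent pair in *species_order*.

    ``species_order`` lists sequence ids top-to-bottom as drawn; a connector
    is flagged inverted when either endpoint's placement is inverted
    relative to the reference (the diagrams' red lines).  Repeated blocks
    contribute their leftmost placement, noted in ``n_placements``.
    """
    rows: list[dict] = []
    for bi, block in enumerate(blocks):
        missing = [sid for sid in species_order if sid not in block.placements]
        if missing:
            raise ValueError(f"species {missing} missing from block placements")
        for upper, lower in zip(species_order, species_order[1:]):
            p_up = block.placements[upper][0]
            p_lo = block.placements[lower][0]
            rows.append({
                "block_index": bi,
                "block_seq": block.block_seq,
                "length": block.length,
                "seq_id_upper": upper, "start_upper": p_up.start,
                "seq_id_lower": lower, "start_lower": p_lo.start,
                "n_placements": max(len(block.placements[upper]),
                                    len(block.placements[lower])),
                "inverted": p_up.inverted or p_lo.inverted,
            })
    return rows
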