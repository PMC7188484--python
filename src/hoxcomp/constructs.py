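"""Deterministic reporter-construct design: truncations, deletions,
successive non-complementary transversion windows, and targeted
substitutions.

The non-complementary transversion replaces each base by the transversion
partner that is *not* its Watson-Crick complement — A<->C and G<->T, the
unique map that is both a transversion and non-complementary.  Applied to
TTAA it yields GGCC, the printed core-motif substitution.  The map is an
involution with no fixed points, so a mutated window shares zero positions
with the original and a second application restores it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

from .seqio import GenomicSequence

_TRANSVERSION = str.maketrans("ACGT", "CATG")

EditKind = Literal["truncate_to", "delete", "transverse", "substitute"]


class EditError(ValueError):
    pass


def noncomp_transversion(residues: str) -> str:
    """Positionwise A<->C, G<->T; errors on any base outside {A,C,G,T}."""
    bad = set(residues) - set("ACGT")
    if bad:
        raise EditError(
            f"non-complementary transversion undefined for {sorted(bad)} "
            "(ambiguous bases cannot be mutated)"
        )
    return residues.translate(_TRANSVERSION)


def tile_windows(region: tuple[int, int], width: int,
                 strict: bool = True) -> list[tuple[int, int]]:
    """Consecutive disjoint windows of exactly *width* across *region*.

    In strict mode a remainder is an error; in lenient mode the final short
    window is appended (callers can recognise it by its length).
    """
    start, end = region
    if width < 1:
        raise EditError("window width must be >= 1")
    if start < 0 or start >= end:
        raise EditError(f"invalid region [{start}, {end})")
    length = end - start
    remainder = length % width
    if strict and remainder:
        raise EditError(
            f"region length {length} is not divisible by width {width} "
            f"(remainder {remainder})"
        )
    windows = [(start + i * width, start + (i + 1) * width)
               for i in range(length // width)]
    if remainder:
        windows.append((end - remainder, end))
    return windows


@dataclass(frozen=True)
class EditOperation:
    """One edit on the base sequence (all intervals in base coordinates)."""

    kind: EditKind
    start: int
    end: int
    payload: str = ""   # replacement residues, substitute only
    expected: str = ""  # required original residues, substitute only

    def __post_init__(self) -> None:
        if self.kind not in ("truncate_to", "delete", "transverse", "substitute"):
            raise EditError(f"unknown edit kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise EditError(f"invalid edit interval [{self.start}, {self.end})")
        if self.kind == "substitute":
            if len(self.payload) != self.end - self.start:
                raise EditError("substitute payload length must equal interval length")
            if not self.expected:
                raise EditError(
                    "substitute edits must state the expected original residues"
                )
            if len(self.expected) != self.end - self.start:
                raise EditError("expected residues length must equal interval length")
        elif self.payload:
            raise EditError(f"{self.kind} edits take no payload")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class ConstructSpec:
    name: str
    base_seq_id: str
    edits: tuple[EditOperation, ...]


def apply_edits(base: GenomicSequence, spec: ConstructSpec) -> str:
    """Apply a construct's edit list to its base sequence.

    All intervals refer to base coordinates; edits must not overlap and at
    most one ``truncate_to`` is allowed (the kept window).  Substitute edits
    are guarded against coordinate drift by their stated original residues.
    """
    if spec.base_seq_id != base.id:
        raise EditError(f"construct {spec.name!r} targets {spec.base_seq_id!r}, "
                        f"got sequence {base.id!r}")
    residues = base.residues
    n = len(residues)
    truncs = [e for e in spec.edits if e.kind == "truncate_to"]
    if len(truncs) > 1:
        raise EditError("at most one truncate_to edit per construct")
    others = sorted((e for e in spec.edits if e.kind != "truncate_to"),
                    key=lambda e: e.start)
    for e in spec.edits:
        if e.end > n:
            raise EditError(f"edit [{e.start},{e.end}) exceeds base length {n}")
    for a, b in zip(others, others[1:]):
        if b.start < a.end:
            raise EditError(f"overlapping edits [{a.start},{a.end}) and [{b.start},{b.end})")

    out = list(residues)
    deleted = [False] * n
    for e in others:
        segment = residues[e.start:e.end]
        if e.kind == "delete":
            for i in range(e.start, e.end):
                deleted[i] = True
        elif e.kind == "transverse":
            out[e.start:e.end] = noncomp_transversion(segment)
        elif e.kind == "substitute":
            if segment != e.expected:
                raise EditError(
                    f"coordinate drift in {spec.name!r}: base has {segment!r} at "
                    f"[{e.start},{e.end}), edit expected {e.expected!r}"
                )
            out[e.start:e.end] = e.payload
    lo, hi = (truncs[0].start, truncs[0].end) if truncs else (0, n)
    return "".join(out[i] for i in range(lo, hi) if not deleted[i])


def fg_tiling_series(
    base: GenomicSequence,
    region: tuple[int, int],
    width: int = 47,
    name_prefix: str = "FG",
    strict: bool = True,
) -> list[ConstructSpec]:
    """Successive transversion-window constructs along *region*.

    One construct per window: construct i carries a single ``transverse``
    edit over window i, so any two products differ from the base only in
    their own windows.
    """
    windows = tile_windows(region, width, strict=strict)
    return [
        ConstructSpec(
            name=f"{name_prefix}{i + 1}",
            base_seq_id=base.id,
            edits=(EditOperation("transverse", w_start, w_end),),
        )
        for i, (w_start, w_end) in enumerate(windows)
    ]


def substitution_construct(
    base: GenomicSequence,
    name: str,
    at: int,
    old: str,
    new: str,
) -> ConstructSpec:
    """A targeted substitution construct (e.g. the TTAA>GGCC core mutation)."""
    return ConstructSpec(
        name=name,
        base_seq_id=base.id,
        edits=(EditOperation("substitute", at, at + len(old),
                             payload=new, expected=old),),
    )
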