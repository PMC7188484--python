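"""Cross-species grouping of motif instances into putative orthologs.

Motif hits are anchored to a gene feature (offset from the anchor's 5'
boundary in its reading orientation) and compared by ungapped flanking-
sequence identity; instances from different species at similar relative
locations with similar flanks are chained into ortholog groups by
single-linkage clustering.  Thresholds are package decisions, exposed as
parameters: the field practice they encode is "similar relative location
and similar core + flanking sequence".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .motif import MotifHit, revcomp
from .seqio import FeatureAnnotation, GenomicSequence

DEFAULT_OFFSET_TOL_BP = 2_000
DEFAULT_FLANK_LEN = 20
DEFAULT_MIN_FLANK_ID = 0.6


@dataclass(frozen=True)
class AnchoredHit:
    """A motif hit with anchor-relative position and extracted flanks.

    Flanks are read in the hit's strand orientation (upstream = 5' of the
    motif on its own strand), so they stay comparable across inverted loci.
    Truncated flanks (hit near a sequence end) are flagged.
    """

    hit: MotifHit
    species: str
    anchor_gene: str = ""
    anchor_feature: str = ""
    signed_offset_bp: int | None = None
    flank_up: str = ""
    flank_down: str = ""
    truncated: bool = False
    anchored: bool = True


@dataclass(frozen=True)
class OrthologGroup:
    group_id: str
    members: tuple[AnchoredHit, ...]
    mean_offset: float
    min_pairwise_flank_identity: float

    @property
    def species(self) -> frozenset[str]:
        return frozenset(m.species for m in self.members)


def _extract_flanks(seq: GenomicSequence, hit: MotifHit,
                    flank_len: int) -> tuple[str, str, bool]:
    up = seq.residues[max(0, hit.start - flank_len):hit.start]
    down = seq.residues[hit.end:hit.end + flank_len]
    if hit.strand == "-":
        up, down = revcomp(down), revcomp(up)
    truncated = len(up) < flank_len or len(down) < flank_len
    return up, down, truncated


def anchor_hits(
    hits: Sequence[MotifHit],
    features: Sequence[FeatureAnnotation],
    anchor_spec: tuple[str, str],
    seqs: Sequence[GenomicSequence],
    flank_len: int = DEFAULT_FLANK_LEN,
    species_of: Mapping[str, str] | None = None,
) -> list[AnchoredHit]:
    """Anchor each hit to the nearest matching feature on its sequence.

    The offset is the hit start minus the anchor's 5' reference point, with
    the sign flipped when the anchor is on the minus strand (so positive
    always means downstream of the anchor in its reading orientation).
    Hits on sequences without a matching anchor are emitted unanchored.
    """
    gene, kind = anchor_spec
    from .seqio import FEATURE_KINDS, GENE_LABELS
    if gene not in GENE_LABELS or kind not in FEATURE_KINDS:
        raise ValueError(f"unknown anchor spec {anchor_spec!r}")
    seq_by_id = {s.id: s for s in seqs}
    anchors_by_seq: dict[str, list[FeatureAnnotation]] = {}
    for f in features:
        if f.gene == gene and f.feature_kind == kind:
            anchors_by_seq.setdefault(f.seq_id, []).append(f)

    out: list[AnchoredHit] = []
    for hit in hits:
        seq = seq_by_id.get(hit.seq_id)
        if seq is None:
            raise ValueError(f"hit references unknown sequence {hit.seq_id!r}")
        sp = (species_of or {}).get(hit.seq_id, seq.species)
        up, down, truncated = _extract_flanks(seq, hit, flank_len)
        anchors = anchors_by_seq.get(hit.seq_id, [])
        if not anchors:
            out.append(AnchoredHit(hit=hit, species=sp, flank_up=up,
                                   flank_down=down, truncated=truncated,
                                   anchored=False))
            continue

        def offset_to(a: FeatureAnnotation) -> int:
            # 5' boundary: start on '+', end on '-'; '.' treated as '+'
            if a.strand == "-":
                return a.end - hit.start
            return hit.start - a.start

        best = min(anchors, key=lambda a: (abs(offset_to(a)), a.start))
        out.append(AnchoredHit(
            hit=hit, species=sp, anchor_gene=gene, anchor_feature=kind,
            signed_offset_bp=offset_to(best),
            flank_up=up, flank_down=down, truncated=truncated,
        ))
    return out


def flank_identity(a: AnchoredHit, b: AnchoredHit) -> float | None:
    """Ungapped identity over aligned up+down flanks.

    Up-flanks align at their motif-proximal (right) edge, down-flanks at
    their left edge; truncated flanks are compared over the overlapping
    length.  Returns None when no flank positions overlap.
    """
    up_n = min(len(a.flank_up), len(b.flank_up))
    down_n = min(len(a.flank_down), len(b.flank_down))
    total = up_n + down_n
    if total == 0:
        return None
    matches = sum(x == y for x, y in zip(a.flank_up[-up_n:] if up_n else "",
                                         b.flank_up[-up_n:] if up_n else ""))
    matches += sum(x == y for x, y in zip(a.flank_down[:down_n],
                                          b.flank_down[:down_n]))
    return matches / total


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        self.parent[self.find(i)] = self.find(j)


def group_orthologous_hits(
    anchored: Sequence[AnchoredHit],
    offset_tol_bp: int = DEFAULT_OFFSET_TOL_BP,
    min_flank_id: float = DEFAULT_MIN_FLANK_ID,
) -> list[OrthologGroup]:
    """Single-linkage clustering of anchored hits into ortholog groups.

    Two hits are compatible when their anchor offsets differ by at most
    ``offset_tol_bp`` and their flank identity reaches ``min_flank_id``.
    Connected components spanning >= 2 species are emitted, numbered by
    leftmost mean offset.
    """
    nodes = [a for a in anchored if a.anchored and a.signed_offset_bp is not None]
    uf = _UnionFind(len(nodes))
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if abs(nodes[i].signed_offset_bp - nodes[j].signed_offset_bp) > offset_tol_bp:
                continue
            ident = flank_identity(nodes[i], nodes[j])
            if ident is not None and ident >= min_flank_id:
                uf.union(i, j)
    components: dict[int, list[AnchoredHit]] = {}
    for i, node in enumerate(nodes):
        components.setdefault(uf.find(i), []).append(node)

    groups: list[tuple[float, list[AnchoredHit]]] = []
    for members in components.values():
        if len({m.species for m in members}) < 2:
            continue
        mean_off = sum(m.signed_offset_bp for m in members) / len(members)
        groups.append((mean_off, members))
    groups.sort(key=lambda g: g[0])

    out: list[OrthologGroup] = []
    for gi, (mean_off, members) in enumerate(groups, start=1):
        idents = [flank_identity(a, b)
                  for k, a in enumerate(members) for b in members[k + 1:]]
        idents = [x for x in idents if x is not None]
        out.append(OrthologGroup(
            group_id=f"group_{gi}",
            members=tuple(sorted(members,
                                 key=lambda m: (m.species, m.hit.seq_id, m.hit.start))),
            mean_offset=mean_off,
            min_pairwise_flank_identity=min(idents) if idents else float("nan"),
        ))
    return out
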