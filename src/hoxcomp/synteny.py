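"""Hox2/Hox3 scaffold-configuration classification.

Each species' annotated scaffolds are classified against a fixed rule
order for the focal gene pair (*pb*/Hox2 and *zen*/Hox3):

1. ``syntenic`` — both homeodomain exons on one scaffold; relative
   orientation read off the strands.
2. ``likely_adjacent`` — homeodomains on separate scaffolds, but the zen
   scaffold carries a pb-type YPWM-encoding exon near one scaffold end
   (within ``adjacency_window_bp``), the classic sign of a split assembly
   rather than a real rearrangement.
3. ``gene_loss`` — every feature of one focal gene absent from the species.
4. ``unresolved`` — both genes present but no co-scaffolding or adjacency
   evidence.  Translocation is never inferred positively.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .seqio import FeatureAnnotation

FOCAL_GENES = ("pb", "zen")
CLASSIFICATIONS = ("syntenic", "likely_adjacent", "gene_loss", "unresolved")

DEFAULT_ADJACENCY_WINDOW_BP = 20_000


@dataclass(frozen=True)
class SyntenyRecord:
    species: str
    classification: str
    lost_genes: frozenset[str] = frozenset()
    scaffolds_used: frozenset[str] = frozenset()
    relative_orientation: str = "unknown"  # 'same' | 'opposite' | 'unknown'
    clade: str = ""

    def __post_init__(self) -> None:
        if self.classification not in CLASSIFICATIONS:
            raise ValueError(f"invalid classification {self.classification!r}")
        if (self.classification == "gene_loss") != bool(self.lost_genes):
            raise ValueError("classification is gene_loss iff lost_genes nonempty")


def _homeodomains(features: Sequence[FeatureAnnotation], gene: str) -> list[FeatureAnnotation]:
    return [f for f in features if f.gene == gene and f.feature_kind == "homeodomain_exon"]


def classify_species(
    features: Sequence[FeatureAnnotation],
    adjacency_window_bp: int = DEFAULT_ADJACENCY_WINDOW_BP,
    scaffold_lengths: Mapping[str, int] | None = None,
    species: str | None = None,
    clade: str = "",
) -> SyntenyRecord:
    """Classify one species' Hox2/Hox3 configuration.

    *features* must all belong to one species.  ``scaffold_lengths`` is
    needed to judge proximity to the right scaffold end; without it only
    distance to the scaffold start is considered.
    """
    features = list(features)
    if not features:
        raise ValueError("no features provided for species")
    sp = species if species is not None else features[0].species
    if any(f.species != features[0].species for f in features):
        raise ValueError("features from multiple species passed to classify_species")
    scaffolds = frozenset(f.seq_id for f in features)

    pb_hd = _homeodomains(features, "pb")
    zen_hd = _homeodomains(features, "zen")

    # rule 1: co-scaffolded homeodomains
    shared = {f.seq_id for f in pb_hd} & {f.seq_id for f in zen_hd}
    if shared:
        sid = sorted(shared)[0]
        s_pb = next(f.strand for f in pb_hd if f.seq_id == sid)
        s_zen = next(f.strand for f in zen_hd if f.seq_id == sid)
        if "." in (s_pb, s_zen):
            orient = "unknown"
        else:
            orient = "same" if s_pb == s_zen else "opposite"
        return SyntenyRecord(sp, "syntenic", scaffolds_used=scaffolds,
                             relative_orientation=orient, clade=clade)

    # rule 2: zen scaffold carries a pb-type YPWM ORF near a scaffold end
    if pb_hd and zen_hd:
        zen_scaffolds = {f.seq_id for f in zen_hd}
        for f in features:
            if f.gene != "pb" or f.feature_kind != "ypwm_exon" or f.seq_id not in zen_scaffolds:
                continue
            near_start = f.start < adjacency_window_bp
            near_end = False
            if scaffold_lengths and f.seq_id in scaffold_lengths:
                near_end = scaffold_lengths[f.seq_id] - f.end < adjacency_window_bp
            if near_start or near_end:
                return SyntenyRecord(
                    sp, "likely_adjacent",
                    scaffolds_used=frozenset({f.seq_id} | {g.seq_id for g in pb_hd}),
                    clade=clade,
                )

    # rule 3: total loss of a focal gene
    lost = frozenset(g for g in FOCAL_GENES
                     if not any(f.gene == g for f in features))
    if lost:
        return SyntenyRecord(sp, "gene_loss", lost_genes=lost,
                             scaffolds_used=scaffolds, clade=clade)

    return SyntenyRecord(sp, "unresolved", scaffolds_used=scaffolds, clade=clade)


def classify_all(
    features: Sequence[FeatureAnnotation],
    adjacency_window_bp: int = DEFAULT_ADJACENCY_WINDOW_BP,
    scaffold_lengths: Mapping[str, int] | None = None,
    clades: Mapping[str, str] | None = None,
) -> list[SyntenyRecord]:
    """Group features by species and classify each species."""
    by_species: dict[str, list[FeatureAnnotation]] = {}
    for f in features:
        by_species.setdefault(f.species, []).append(f)
    return [
        classify_species(feats, adjacency_window_bp, scaffold_lengths,
                         species=sp, clade=(clades or {}).get(sp, ""))
        for sp, feats in sorted(by_species.items())
    ]


def summarize_synteny(
    records: Iterable[SyntenyRecord],
    divergence_flag: Mapping[str, str],
) -> pd.DataFrame:
    """Per divergence group ('pre'/'post' Hox3-zen split) classification counts.

    Returns one row per (group, classification) plus one row per lost gene,
    with numerator/denominator columns so fractions like 3/66 stay exact.
    """
    records = list(records)
    for r in records:
        if r.species not in divergence_flag:
            raise ValueError(f"species {r.species!r} missing from divergence_flag")
        if divergence_flag[r.species] not in ("pre", "post"):
            raise ValueError(f"invalid divergence flag for {r.species!r}")
    rows: list[dict] = []
    for group in ("pre", "post"):
        members = [r for r in records if divergence_flag[r.species] == group]
        denom = len(members)
        if denom == 0:
            continue
        for cls in CLASSIFICATIONS:
            num = sum(1 for r in members if r.classification == cls)
            rows.append({"group": group, "category": cls,
                         "count": num, "n_species": denom,
                         "fraction": num / denom})
        lost_counts: dict[str, int] = {}
        for r in members:
            for g in sorted(r.lost_genes):
                lost_counts[g] = lost_counts.get(g, 0) + 1
        for gene, num in sorted(lost_counts.items()):
            rows.append({"group": group, "category": f"lost:{gene}",
                         "count": num, "n_species": denom,
                         "fraction": num / denom})
    return pd.DataFrame(rows, columns=["group", "category", "count", "n_species", "fraction"])
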