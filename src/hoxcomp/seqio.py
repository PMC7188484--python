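"""Sequence and feature I/O with fixed coordinate conventions.

All coordinates are 0-based half-open internally and in machine-readable
output columns; 1-based inclusive coordinates appear only in report columns
suffixed ``_1based``.  Genomic target sequences are restricted to the
{A, C, G, T, N} alphabet (uppercased on ingest): degenerate IUPAC codes are
allowed in search patterns, never in targets.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TARGET_ALPHABET = frozenset("ACGTN")

#: canonical gene labels; common synonyms are folded on ingest
GENE_LABELS = ("pb", "zen", "zen2", "bcd", "Dfd", "other")
_GENE_SYNONYMS = {
    "pb": "pb", "hox2": "pb",
    "zen": "zen", "hox3": "zen",
    "zen2": "zen2", "bcd": "bcd", "bicoid": "bcd",
    "dfd": "Dfd",
    "other": "other",
}

FEATURE_KINDS = ("homeodomain_exon", "ypwm_exon", "gene_span", "other")


class FormatError(ValueError):
    """Malformed input file (names the offending record or line)."""


@dataclass(frozen=True)
class GenomicSequence:
    """A genomic scaffold or enhancer region over {A,C,G,T,N}."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - TARGET_ALPHABET
        if bad:
            raise FormatError(
                f"sequence {self.id!r}: disallowed characters {sorted(bad)} "
                "(targets must be over A/C/G/T/N; degenerate codes belong in patterns)"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class FeatureAnnotation:
    """A located gene feature (BED6 convention: 0-based half-open)."""

    seq_id: str
    start: int
    end: int
    gene: str
    feature_kind: str
    strand: str = "."  # '+', '-', or '.' for unknown
    species: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.gene}|{self.feature_kind} on {self.seq_id}: "
                f"invalid interval [{self.start}, {self.end})"
            )
        if self.gene not in GENE_LABELS:
            raise FormatError(f"unknown gene label {self.gene!r}")
        if self.feature_kind not in FEATURE_KINDS:
            raise FormatError(f"unknown feature kind {self.feature_kind!r}")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


def canonical_gene(label: str) -> str:
    """Fold a gene label to its canonical form; unknown labels become 'other'."""
    key = label.strip().lower()
    if key in _GENE_SYNONYMS:
        return _GENE_SYNONYMS[key]
    warnings.warn(f"unknown gene label {label!r} mapped to 'other'", stacklevel=2)
    return "other"


def read_fasta(path: str | Path, species: str | None = None) -> list[GenomicSequence]:
    """Read a multi-record FASTA into :class:`GenomicSequence` records.

    Residues are uppercased on ingest.  A ``species=`` token in the record
    description sets the species label; the *species* argument overrides it.
    Duplicate IDs or non-{A,C,G,T,N} residues raise :class:`FormatError`.
    """
    path = Path(path)
    records: list[GenomicSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        sp = species if species is not None else _species_from_description(rec.description)
        records.append(GenomicSequence(id=rec.id, residues=str(rec.seq).upper(), species=sp))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _species_from_description(description: str) -> str:
    for token in description.split():
        if token.startswith("species="):
            return token[len("species="):]
    return ""


def write_fasta(seqs: Iterable[GenomicSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(s.residues), id=s.id,
                  description=f"species={s.species}" if s.species else "")
        for s in seqs
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_features(path: str | Path, species: str | None = None) -> list[FeatureAnnotation]:
    """Read a BED6 feature file; the name column encodes ``gene|feature_kind``.

    Intervals are kept verbatim (BED is already 0-based half-open).  Unknown
    gene labels map to 'other' with a warning; structural problems raise
    :class:`FormatError` with the line number.
    """
    path = Path(path)
    feats: list[FeatureAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns, got {len(cols)}")
            seq_id, start_s, end_s, name, _score, strand = cols[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise FormatError(f"{path}:{lineno}: invalid interval [{start}, {end})")
            if "|" not in name:
                raise FormatError(
                    f"{path}:{lineno}: name column {name!r} is not 'gene|feature_kind'"
                )
            gene_raw, kind = name.split("|", 1)
            if kind not in FEATURE_KINDS:
                raise FormatError(f"{path}:{lineno}: unknown feature kind {kind!r}")
            if strand not in ("+", "-", "."):
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            feats.append(FeatureAnnotation(
                seq_id=seq_id, start=start, end=end,
                gene=canonical_gene(gene_raw), feature_kind=kind,
                strand=strand, species=species or "",
            ))
    return feats


def write_features(feats: Iterable[FeatureAnnotation], path: str | Path) -> None:
    """Write features as BED6 with the ``gene|feature_kind`` name encoding."""
    rows = sorted(feats, key=lambda f: (f.seq_id, f.start, f.end))
    with open(path, "w") as fh:
        for f in rows:
            fh.write(f"{f.seq_id}\t{f.start}\t{f.end}\t{f.gene}|{f.feature_kind}\t0\t{f.strand}\n")


def validate_features(feats: Iterable[FeatureAnnotation],
                      seqs: Iterable[GenomicSequence]) -> None:
    """Check that every feature lies within its referenced sequence."""
    lengths: Mapping[str, int] = {s.id: s.length for s in seqs}
    for f in feats:
        if f.seq_id not in lengths:
            raise FormatError(f"feature references unknown sequence {f.seq_id!r}")
        if f.end > lengths[f.seq_id]:
            raise FormatError(
                f"feature [{f.start},{f.end}) exceeds {f.seq_id!r} length {lengths[f.seq_id]}"
            )


def to_dataframe(records: Sequence) -> pd.DataFrame:
    """Convert a homogeneous collection of dataclass records to a DataFrame."""
    if len(records) == 0:
        return pd.DataFrame()
    first = records[0]
    if dataclasses.is_dataclass(first):
        return pd.DataFrame([dataclasses.asdict(r) for r in records])
    return pd.DataFrame(list(records))


_STRAND_ORDER = {"+": 0, "-": 1, ".": 2}


def write_table(records, path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a result collection as a deterministic TSV.

    Rows are sorted by (seq_id, start, strand with '+' first) where those
    columns exist.  For every start/end pair, companion report columns
    ``start_1based``/``end_1based`` are appended (1-based inclusive).
    An empty collection yields a header-only file when *columns* is given,
    otherwise an empty file.
    """
    df = records.copy() if isinstance(records, pd.DataFrame) else to_dataframe(records)
    if df.empty and columns is not None:
        df = pd.DataFrame(columns=list(columns))
    sort_cols = [c for c in ("seq_id", "start") if c in df.columns]
    if not df.empty and sort_cols:
        if "strand" in df.columns:
            df = df.assign(_s=df["strand"].map(_STRAND_ORDER))
            df = df.sort_values(sort_cols + ["_s"], kind="mergesort").drop(columns="_s")
        else:
            df = df.sort_values(sort_cols, kind="mergesort")
    if "start" in df.columns and "end" in df.columns and not df.empty:
        df["start_1based"] = df["start"].astype(int) + 1
        df["end_1based"] = df["end"].astype(int)
    df.to_csv(path, sep="\t", index=False)
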