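"""Synthetic multi-species Hox2/Hox3 locus sets with a ground-truth ledger.

The generator emulates the statistical structure the comparative analysis
assumes: per-species backgrounds diverged from a common ancestor by point
substitution, identical planted blocks (optionally reverse-complemented in
some species), motif instances realized at controlled mismatch distances
and anchor offsets, gene-feature annotations with per-species losses, and
scaffold splits.  Divergence is substitution-only so planted coordinates
stay exact across species.

Every planted element draws from its own seeded substream, so adding or
removing one plant never perturbs the others; the whole output is
byte-identical for a given seed.

Planted block edges are *sealed*: the two background positions flanking a
planted block are forced to differ between species, so the maximal shared
block equals the planted block exactly (without sealing, a flanking base
survives divergence in all species in a non-negligible fraction of
simulations and the recovered block would overrun the planted boundary).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .motif import IUPAC_SETS, MotifPattern, revcomp
from .seqio import FeatureAnnotation, GenomicSequence, write_fasta, write_features

_BASES = "ACGT"


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedGene:
    """A gene feature planted at fixed coordinates, possibly absent in some species."""

    gene: str
    feature_kind: str
    start: int
    end: int
    strand: str = "+"
    absent_species: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PlantedBlock:
    """An identical block copied verbatim into every listed species."""

    start: int
    length: int
    inverted_species: frozenset[str] = frozenset()
    absent_species: frozenset[str] = frozenset()


@dataclass(frozen=True)
class PlantedMotif:
    """A motif instance realized at a controlled mismatch distance.

    The planted start is ``anchor 5' boundary + offset`` when an anchor gene
    is given (and planted), else ``offset`` as an absolute coordinate.
    ``mismatches`` maps species to the exact mismatch count to realize
    (unlisted species get 0).
    """

    pattern: MotifPattern
    offset: int
    strand: str = "+"
    anchor: tuple[str, str] | None = ("pb", "homeodomain_exon")
    mismatches: Mapping[str, int] = field(default_factory=dict)
    absent_species: frozenset[str] = frozenset()


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 8
    scaffold_length_bp: int = 4_000
    background_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    per_base_divergence: float = 0.25
    planted_genes: tuple[PlantedGene, ...] = ()
    planted_blocks: tuple[PlantedBlock, ...] = ()
    planted_motifs: tuple[PlantedMotif, ...] = ()
    scaffold_splits: Mapping[str, int] = field(default_factory=dict)
    adjacency_window_bp: int = 20_000
    seed: int = 0

    def species_names(self) -> list[str]:
        return [f"sp{i + 1:02d}" for i in range(self.n_species)]


@dataclass(frozen=True)
class PlantedElementTruth:
    element_id: str
    kind: str          # 'block' | 'motif' | 'gene'
    species: str
    seq_id: str
    start: int         # coordinates on the emitted sequence (post-split)
    end: int
    orientation: str   # 'forward' | 'inverted' / strand for genes
    realized_seq: str
    n_mismatch: int = 0


@dataclass(frozen=True)
class PlantedTruth:
    elements: tuple[PlantedElementTruth, ...]
    expected_classification: Mapping[str, str]
    expected_lost_genes: Mapping[str, frozenset[str]]

    def of_kind(self, kind: str) -> list[PlantedElementTruth]:
        return [e for e in self.elements if e.kind == kind]


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(list(key)))


def _random_seq(rng: np.random.Generator, length: int, probs) -> np.ndarray:
    return rng.choice(4, size=length, p=np.asarray(probs, dtype=float))


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def _realize_pattern(pattern: MotifPattern, rng: np.random.Generator) -> str:
    return "".join(sorted(IUPAC_SETS[c] & set(_BASES))[rng.integers(len(IUPAC_SETS[c] & set(_BASES)))]
                   for c in pattern.iupac)


def _apply_mismatches(word: str, pattern: MotifPattern, n: int,
                      rng: np.random.Generator) -> str:
    """Mutate exactly *n* positions of *word* to bases outside the pattern set."""
    mutable = [j for j in range(len(word)) if len(IUPAC_SETS[pattern.iupac[j]] & set(_BASES)) < 4]
    if n > len(mutable):
        raise SimulationError(
            f"cannot realize {n} mismatches: only {len(mutable)} non-N pattern positions"
        )
    chars = list(word)
    for j in sorted(rng.choice(len(mutable), size=n, replace=False)):
        pos = mutable[j]
        outside = sorted(set(_BASES) - IUPAC_SETS[pattern.iupac[pos]])
        chars[pos] = outside[rng.integers(len(outside))]
    return "".join(chars)


def _motif_start(m: PlantedMotif, genes: Sequence[PlantedGene]) -> int:
    if m.anchor is None:
        return m.offset
    for g in genes:
        if (g.gene, g.feature_kind) == m.anchor:
            return (g.end - m.offset) if g.strand == "-" else (g.start + m.offset)
    raise SimulationError(f"motif anchor {m.anchor!r} not among planted genes")


def _validate(config: SimulationConfig) -> list[tuple[int, int, str]]:
    """Check plant intervals: within scaffold, pairwise non-overlapping."""
    L = config.scaffold_length_bp
    intervals: list[tuple[int, int, str]] = []
    for i, b in enumerate(config.planted_blocks):
        intervals.append((b.start, b.start + b.length, f"block_{i}"))
    for i, m in enumerate(config.planted_motifs):
        s = _motif_start(m, config.planted_genes)
        intervals.append((s, s + len(m.pattern), f"motif_{i}"))
    for s, e, name in intervals:
        if s < 0 or e > L:
            raise SimulationError(f"{name} interval [{s},{e}) exceeds scaffold length {L}")
    ordered = sorted(intervals)
    for (s1, e1, n1), (s2, e2, n2) in zip(ordered, ordered[1:]):
        if s2 < e1:
            raise SimulationError(f"planted elements {n1} and {n2} overlap")
    for g in config.planted_genes:
        if g.start < 0 or g.end > L or g.start >= g.end:
            raise SimulationError(f"gene feature [{g.start},{g.end}) invalid for scaffold {L}")
    for sp, p in config.scaffold_splits.items():
        if not 0 < p < L:
            raise SimulationError(f"split point {p} outside scaffold for {sp}")
    return intervals


def simulate_locus_set(
    config: SimulationConfig,
) -> tuple[list[GenomicSequence], list[FeatureAnnotation], PlantedTruth]:
    """Generate the multi-species locus set described by *config*."""
    intervals = _validate(config)
    occupied = {(s, e) for s, e, _ in intervals}
    species = config.species_names()
    L = config.scaffold_length_bp
    seed = config.seed
    probs = config.background_base_probs

    # ancestral background, then per-species point divergence
    ancestor = _random_seq(_rng(seed, 0), L, probs)
    per_species: dict[str, np.ndarray] = {}
    for si, sp in enumerate(species):
        rng = _rng(seed, 1, si)
        codes = ancestor.copy()
        mutate = rng.random(L) < config.per_base_divergence
        shifts = rng.integers(1, 4, size=L)
        codes[mutate] = (codes[mutate] + shifts[mutate]) % 4
        per_species[sp] = codes

    elements: list[PlantedElementTruth] = []

    def _seal(pos: int, salt: int) -> None:
        """Force the background base at *pos* to differ between species."""
        if pos < 0 or pos >= L or any(s <= pos < e for s, e in occupied):
            return
        base = int(_rng(seed, 4, salt).integers(4))
        for si, sp in enumerate(species):
            per_species[sp][pos] = (base + si) % 4

    # blocks: identical across species (revcomp in inverted species)
    for bi, b in enumerate(config.planted_blocks):
        rng = _rng(seed, 2, bi)
        block = _decode(_random_seq(rng, b.length, probs))
        for sp in species:
            if sp in b.absent_species:
                continue
            inverted = sp in b.inverted_species
            realized = revcomp(block) if inverted else block
            codes = np.array([_BASES.index(c) for c in realized], dtype=ancestor.dtype)
            per_species[sp][b.start:b.start + b.length] = codes
            elements.append(PlantedElementTruth(
                element_id=f"block_{bi}", kind="block", species=sp,
                seq_id="", start=b.start, end=b.start + b.length,
                orientation="inverted" if inverted else "forward",
                realized_seq=realized,
            ))
        _seal(b.start - 1, 2 * bi)
        _seal(b.start + b.length, 2 * bi + 1)

    # motifs: one realized core word, per-species controlled mismatches
    for mi, m in enumerate(config.planted_motifs):
        rng = _rng(seed, 3, mi)
        core = _realize_pattern(m.pattern, rng)
        start = _motif_start(m, config.planted_genes)
        k = len(m.pattern)
        for si, sp in enumerate(species):
            if sp in m.absent_species:
                continue
            n_mm = int(m.mismatches.get(sp, 0))
            word = _apply_mismatches(core, m.pattern, n_mm, _rng(seed, 3, mi, si))
            realized = revcomp(word) if m.strand == "-" else word
            codes = np.array([_BASES.index(c) for c in realized], dtype=ancestor.dtype)
            per_species[sp][start:start + k] = codes
            elements.append(PlantedElementTruth(
                element_id=f"motif_{mi}", kind="motif", species=sp,
                seq_id="", start=start, end=start + k,
                orientation="forward" if m.strand == "+" else "inverted",
                realized_seq=realized, n_mismatch=n_mm,
            ))

    # assemble sequences, applying per-species scaffold splits
    seqs: list[GenomicSequence] = []
    feats: list[FeatureAnnotation] = []
    seq_id_of: dict[tuple[str, int], tuple[str, int]] = {}  # (sp, coord) unused; see _locate

    def _locate(sp: str, start: int, end: int) -> tuple[str, int, int]:
        split = config.scaffold_splits.get(sp)
        if split is None:
            return f"{sp}_scaf1", start, end
        if end <= split:
            return f"{sp}_scaf1", start, end
        if start >= split:
            return f"{sp}_scaf2", start - split, end - split
        raise SimulationError(
            f"element [{start},{end}) spans the {sp} split point {split}"
        )

    for sp in species:
        text = _decode(per_species[sp])
        split = config.scaffold_splits.get(sp)
        if split is None:
            seqs.append(GenomicSequence(f"{sp}_scaf1", text, species=sp))
        else:
            seqs.append(GenomicSequence(f"{sp}_scaf1", text[:split], species=sp))
            seqs.append(GenomicSequence(f"{sp}_scaf2", text[split:], species=sp))
        for gi, g in enumerate(config.planted_genes):
            if sp in g.absent_species:
                continue
            sid, s, e = _locate(sp, g.start, g.end)
            feats.append(FeatureAnnotation(
                seq_id=sid, start=s, end=e, gene=g.gene,
                feature_kind=g.feature_kind, strand=g.strand, species=sp,
            ))
            elements.append(PlantedElementTruth(
                element_id=f"gene_{gi}", kind="gene", species=sp,
                seq_id=sid, start=s, end=e, orientation=g.strand,
                realized_seq="",
            ))

    # re-coordinate block/motif truth onto emitted sequences
    final_elements: list[PlantedElementTruth] = []
    for el in elements:
        if el.kind == "gene":
            final_elements.append(el)
            continue
        sid, s, e = _locate(el.species, el.start, el.end)
        final_elements.append(replace(el, seq_id=sid, start=s, end=e))

    truth = PlantedTruth(
        elements=tuple(final_elements),
        expected_classification=_expected_classes(config),
        expected_lost_genes=_expected_losses(config),
    )
    return seqs, feats, truth


def _expected_losses(config: SimulationConfig) -> dict[str, frozenset[str]]:
    out: dict[str, frozenset[str]] = {}
    for sp in config.species_names():
        present = {g.gene for g in config.planted_genes if sp not in g.absent_species}
        out[sp] = frozenset(g for g in ("pb", "zen")
                            if g not in present and any(x.gene == g for x in config.planted_genes))
    return out


def _expected_classes(config: SimulationConfig) -> dict[str, str]:
    """Structurally derive the expected synteny class for each species."""
    out: dict[str, str] = {}
    losses = _expected_losses(config)
    for sp in config.species_names():
        split = config.scaffold_splits.get(sp)

        def side(pos: int) -> int:
            return 0 if split is None or pos < split else 1

        pb_hd = [g for g in config.planted_genes
                 if g.gene == "pb" and g.feature_kind == "homeodomain_exon"
                 and sp not in g.absent_species]
        zen_hd = [g for g in config.planted_genes
                  if g.gene == "zen" and g.feature_kind == "homeodomain_exon"
                  and sp not in g.absent_species]
        if pb_hd and zen_hd and any(side(p.start) == side(z.start)
                                    for p in pb_hd for z in zen_hd):
            out[sp] = "syntenic"
            continue
        if pb_hd and zen_hd and split is not None:
            zen_sides = {side(z.start) for z in zen_hd}
            adjacent = False
            for g in config.planted_genes:
                if g.gene != "pb" or g.feature_kind != "ypwm_exon" or sp in g.absent_species:
                    continue
                if side(g.start) not in zen_sides:
                    continue
                bounds = (0, split) if side(g.start) == 0 else (split, config.scaffold_length_bp)
                if (g.start - bounds[0] < config.adjacency_window_bp
                        or bounds[1] - g.end < config.adjacency_window_bp):
                    adjacent = True
            if adjacent:
                out[sp] = "likely_adjacent"
                continue
        if losses[sp]:
            out[sp] = "gene_loss"
            continue
        out[sp] = "unresolved"
    return out


def write_outputs(
    seqs: list[GenomicSequence],
    feats: list[FeatureAnnotation],
    truth: PlantedTruth,
    out_dir: str | Path,
    config: SimulationConfig | None = None,
) -> None:
    """Write FASTA, BED6, a truth TSV and the resolved config under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_fasta(seqs, out_dir / "loci.fa")
    write_features(feats, out_dir / "features.bed")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("element_id\tkind\tspecies\tseq_id\tstart\tend\torientation\t"
                 "realized_seq\tn_mismatch\texpected_class\n")
        for el in sorted(truth.elements,
                         key=lambda e: (e.element_id, e.species, e.seq_id, e.start)):
            fh.write(f"{el.element_id}\t{el.kind}\t{el.species}\t{el.seq_id}\t"
                     f"{el.start}\t{el.end}\t{el.orientation}\t{el.realized_seq}\t"
                     f"{el.n_mismatch}\t{truth.expected_classification[el.species]}\n")
    if config is not None:
        with open(out_dir / "config.yaml", "w") as fh:
            yaml.safe_dump(_config_to_dict(config), fh, sort_keys=True)


def _config_to_dict(config: SimulationConfig) -> dict:
    return {
        "n_species": config.n_species,
        "scaffold_length_bp": config.scaffold_length_bp,
        "background_base_probs": list(config.background_base_probs),
        "per_base_divergence": config.per_base_divergence,
        "adjacency_window_bp": config.adjacency_window_bp,
        "seed": config.seed,
        "planted_genes": [
            {"gene": g.gene, "feature_kind": g.feature_kind, "start": g.start,
             "end": g.end, "strand": g.strand,
             "absent_species": sorted(g.absent_species)}
            for g in config.planted_genes
        ],
        "planted_blocks": [
            {"start": b.start, "length": b.length,
             "inverted_species": sorted(b.inverted_species),
             "absent_species": sorted(b.absent_species)}
            for b in config.planted_blocks
        ],
        "planted_motifs": [
            {"pattern": m.pattern.iupac, "name": m.pattern.name,
             "max_mismatch": m.pattern.max_mismatch, "offset": m.offset,
             "strand": m.strand, "anchor": list(m.anchor) if m.anchor else None,
             "mismatches": dict(m.mismatches),
             "absent_species": sorted(m.absent_species)}
            for m in config.planted_motifs
        ],
        "scaffold_splits": dict(config.scaffold_splits),
    }


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Inverse of the resolved-config serialisation (YAML run configs)."""
    return SimulationConfig(
        n_species=d.get("n_species", 8),
        scaffold_length_bp=d.get("scaffold_length_bp", 4_000),
        background_base_probs=tuple(d.get("background_base_probs", (0.25,) * 4)),
        per_base_divergence=d.get("per_base_divergence", 0.25),
        adjacency_window_bp=d.get("adjacency_window_bp", 20_000),
        seed=d.get("seed", 0),
        planted_genes=tuple(
            PlantedGene(g["gene"], g["feature_kind"], g["start"], g["end"],
                        g.get("strand", "+"),
                        frozenset(g.get("absent_species", ())))
            for g in d.get("planted_genes", ())
        ),
        planted_blocks=tuple(
            PlantedBlock(b["start"], b["length"],
                         frozenset(b.get("inverted_species", ())),
                         frozenset(b.get("absent_species", ())))
            for b in d.get("planted_blocks", ())
        ),
        planted_motifs=tuple(
            PlantedMotif(MotifPattern(m.get("name", f"pat{i}"), m["pattern"],
                                      m.get("max_mismatch", 0)),
                         offset=m["offset"], strand=m.get("strand", "+"),
                         anchor=tuple(m["anchor"]) if m.get("anchor") else None,
                         mismatches=dict(m.get("mismatches", {})),
                         absent_species=frozenset(m.get("absent_species", ())))
            for i, m in enumerate(d.get("planted_motifs", ()))
        ),
        scaffold_splits=dict(d.get("scaffold_splits", {})),
    )


def hox_locus_config(seed: int = 0, n_species: int = 8,
                     scaffold_length_bp: int = 4_000,
                     per_base_divergence: float = 0.25) -> SimulationConfig:
    """A ready-made locus layout echoing the analysed gene arrangement.

    One scaffold per species carrying a pb-type YPWM exon, the pb
    homeodomain exon and the zen homeodomain exon, a conserved enhancer
    motif planted in the large intron between the YPWM and homeodomain
    exons, and two conserved blocks (one inverted in the last two species).
    """
    return SimulationConfig(
        n_species=n_species,
        scaffold_length_bp=scaffold_length_bp,
        per_base_divergence=per_base_divergence,
        seed=seed,
        planted_genes=(
            PlantedGene("pb", "ypwm_exon", 200, 260, "+"),
            PlantedGene("pb", "homeodomain_exon", 2_600, 2_780, "+"),
            PlantedGene("zen", "homeodomain_exon", 3_300, 3_480, "+"),
        ),
        planted_blocks=(
            PlantedBlock(start=900, length=20),
            PlantedBlock(start=1_800, length=24,
                         inverted_species=frozenset(
                             f"sp{i + 1:02d}" for i in range(max(0, n_species - 2), n_species))),
        ),
        planted_motifs=(
            PlantedMotif(MotifPattern("EO053", "ATCATTAATCAT", 1),
                         offset=-1_300, strand="+",
                         anchor=("pb", "homeodomain_exon"),
                         mismatches={"sp03": 1} if n_species >= 3 else {}),
        ),
    )
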