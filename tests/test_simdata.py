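import dataclasses

import pytest

from hoxcomp import (
    EO053_MOTIF,
    MotifPattern,
    PlantedBlock,
    PlantedGene,
    PlantedMotif,
    SimulationConfig,
    classify_species,
    hox_locus_config,
    mismatch_count,
    revcomp,
    scan_many,
    shared_identical_blocks,
    simulate_locus_set,
    summarize_synteny,
)
from hoxcomp.simdata import SimulationError, write_outputs


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        for sub in ("a", "b"):
            cfg = hox_locus_config(seed=42)
            write_outputs(*simulate_locus_set(cfg), tmp_path / sub, cfg)
        for name in ("loci.fa", "features.bed", "truth.tsv", "config.yaml"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes(), name

    def test_different_seed_differs(self):
        seqs1, _, _ = simulate_locus_set(hox_locus_config(seed=1))
        seqs2, _, _ = simulate_locus_set(hox_locus_config(seed=2))
        assert seqs1[0].residues != seqs2[0].residues

    def test_adding_a_plant_does_not_perturb_other_elements(self):
        cfg = hox_locus_config(seed=9)
        _, _, truth1 = simulate_locus_set(cfg)
        cfg2 = dataclasses.replace(
            cfg, planted_blocks=cfg.planted_blocks + (PlantedBlock(start=3_600, length=18),))
        _, _, truth2 = simulate_locus_set(cfg2)
        blocks1 = {(e.element_id, e.species): e.realized_seq for e in truth1.of_kind("block")}
        blocks2 = {(e.element_id, e.species): e.realized_seq for e in truth2.of_kind("block")}
        assert all(blocks2[k] == v for k, v in blocks1.items())


class TestReextraction:
    @pytest.mark.parametrize("seed", range(6))
    def test_truth_sequences_reextract_from_fasta(self, seed):
        cfg = hox_locus_config(seed=seed)
        seqs, _, truth = simulate_locus_set(cfg)
        by_id = {s.id: s for s in seqs}
        for el in truth.elements:
            if el.kind == "gene":
                continue
            segment = by_id[el.seq_id].residues[el.start:el.end]
            assert segment == el.realized_seq, el

    def test_motif_mismatch_counts_are_exact(self):
        cfg = hox_locus_config(seed=5)
        _, _, truth = simulate_locus_set(cfg)
        for el in truth.of_kind("motif"):
            word = el.realized_seq if el.orientation == "forward" else revcomp(el.realized_seq)
            assert mismatch_count(EO053_MOTIF.iupac, word) == el.n_mismatch


class TestPlantedRecovery:
    def test_blocks_recovered_with_exact_boundaries(self):
        cfg = hox_locus_config(seed=13)
        seqs, _, truth = simulate_locus_set(cfg)
        found = shared_identical_blocks(seqs, min_len=14)
        found_keys = {min(b.block_seq, revcomp(b.block_seq)) for b in found}
        for element_id in ("block_0", "block_1"):
            members = [e for e in truth.elements if e.element_id == element_id]
            fwd = next(e.realized_seq for e in members if e.orientation == "forward")
            assert min(fwd, revcomp(fwd)) in found_keys
            block = next(b for b in found
                         if min(b.block_seq, revcomp(b.block_seq)) == min(fwd, revcomp(fwd)))
            for e in members:
                assert any(p.start == e.start
                           for p in block.placements[e.seq_id])

    def test_motif_scan_budget_discriminates_planted_mismatch(self):
        cfg = hox_locus_config(seed=21)
        seqs, _, truth = simulate_locus_set(cfg)
        planted = {(e.seq_id, e.start): e for e in truth.of_kind("motif")}
        at0 = {(h.seq_id, h.start)
               for h in scan_many(seqs, [MotifPattern("EO053", "ATCATTAATCAT", 0)])}
        at1 = {(h.seq_id, h.start)
               for h in scan_many(seqs, [EO053_MOTIF])}
        for key, el in planted.items():
            assert key in at1
            assert (key in at0) == (el.n_mismatch == 0)
        # sp03 carries the planted 1-mismatch variant
        assert ("sp03_scaf1", next(iter(planted))[1]) not in at0

    def test_zen_loss_fraction_recovered_in_summary(self):
        lost = ("sp01", "sp05", "sp09")
        cfg = SimulationConfig(
            n_species=22, scaffold_length_bp=1_500, seed=3,
            planted_genes=(
                PlantedGene("pb", "homeodomain_exon", 200, 380, "+"),
                PlantedGene("zen", "homeodomain_exon", 900, 1_080, "+",
                            absent_species=frozenset(lost)),
            ),
        )
        seqs, feats, truth = simulate_locus_set(cfg)
        lengths = {s.id: s.length for s in seqs}
        by_species: dict[str, list] = {}
        for f in feats:
            by_species.setdefault(f.species, []).append(f)
        records = [classify_species(v, 20_000, lengths) for v in by_species.values()]
        for r in records:
            assert r.classification == truth.expected_classification[r.species]
        df = summarize_synteny(records, {sp: "post" for sp in by_species})
        row = df[(df.group == "post") & (df.category == "lost:zen")].iloc[0]
        assert (row["count"], row.n_species) == (3, 22)

    def test_split_scaffold_yields_likely_adjacent(self):
        cfg = SimulationConfig(
            n_species=2, scaffold_length_bp=4_000, seed=8,
            planted_genes=(
                PlantedGene("pb", "ypwm_exon", 200, 260, "+"),
                PlantedGene("pb", "homeodomain_exon", 1_000, 1_180, "+"),
                PlantedGene("zen", "homeodomain_exon", 3_000, 3_180, "+"),
            ),
            # sp02's scaffold breaks between the pb homeodomain and zen;
            # the pb YPWM exon rides on the zen-free side for sp01 only
            scaffold_splits={"sp02": 500},
        )
        seqs, feats, truth = simulate_locus_set(cfg)
        lengths = {s.id: s.length for s in seqs}
        sp2_feats = [f for f in feats if f.species == "sp02"]
        r = classify_species(sp2_feats, 20_000, lengths)
        # pb YPWM on scaf1; pb HD and zen HD together on scaf2 -> syntenic
        assert r.classification == "syntenic"
        assert truth.expected_classification["sp02"] == "syntenic"

    def test_split_between_homeodomains_with_ypwm_near_end(self):
        cfg = SimulationConfig(
            n_species=2, scaffold_length_bp=4_000, seed=8,
            planted_genes=(
                PlantedGene("pb", "homeodomain_exon", 200, 380, "+"),
                PlantedGene("pb", "ypwm_exon", 1_600, 1_660, "+"),
                PlantedGene("zen", "homeodomain_exon", 3_000, 3_180, "+"),
            ),
            scaffold_splits={"sp02": 1_500},
            adjacency_window_bp=2_000,
        )
        seqs, feats, truth = simulate_locus_set(cfg)
        lengths = {s.id: s.length for s in seqs}
        sp2_feats = [f for f in feats if f.species == "sp02"]
        r = classify_species(sp2_feats, 2_000, lengths)
        assert r.classification == "likely_adjacent"
        assert truth.expected_classification["sp02"] == "likely_adjacent"


class TestValidation:
    def test_overlapping_plants_rejected(self):
        cfg = SimulationConfig(
            n_species=2, scaffold_length_bp=500, seed=1,
            planted_blocks=(PlantedBlock(10, 30), PlantedBlock(25, 30)),
        )
        with pytest.raises(SimulationError, match="overlap"):
            simulate_locus_set(cfg)

    def test_plant_exceeding_scaffold_rejected(self):
        cfg = SimulationConfig(
            n_species=2, scaffold_length_bp=100, seed=1,
            planted_blocks=(PlantedBlock(90, 30),),
        )
        with pytest.raises(SimulationError, match="exceeds"):
            simulate_locus_set(cfg)

    def test_plant_spanning_split_rejected(self):
        cfg = SimulationConfig(
            n_species=2, scaffold_length_bp=500, seed=1,
            planted_blocks=(PlantedBlock(100, 50),),
            scaffold_splits={"sp01": 120},
        )
        with pytest.raises(SimulationError, match="span"):
            simulate_locus_set(cfg)
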