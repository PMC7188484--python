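import numpy as np
import pytest

from hoxcomp import (
    GenomicSequence,
    blocks_to_connectors,
    revcomp,
    shared_identical_blocks,
)

from .conftest import random_dna
from .oracles import naive_revcomp, naive_shared_blocks


def plant(background: str, insert: str, at: int) -> str:
    return background[:at] + insert + background[at + len(insert):]


def canonical_blocks(blocks):
    """Orientation-free comparison form: {min(seq, rc): {sid: {starts}}}."""
    out = {}
    for b in blocks:
        key = min(b.block_seq, revcomp(b.block_seq))
        out[key] = {sid: {p.start for p in places}
                    for sid, places in b.placements.items()}
    return out


def canonical_oracle(oracle):
    return {min(w, naive_revcomp(w)): {sid: {s for s, _ in places}
                                       for sid, places in occ.items()}
            for w, occ in oracle.items()}


class TestPlantedBlocks:
    def test_planted_20mer_found_with_exact_boundaries(self, rng):
        block = random_dna(rng, 20)
        seqs = [GenomicSequence(f"s{i}", plant(random_dna(rng, 200), block, 40 + 30 * i))
                for i in range(3)]
        found = shared_identical_blocks(seqs, min_len=14)
        assert len(found) == 1
        assert found[0].block_seq == block
        for i, s in enumerate(seqs):
            (p,) = found[0].placements[s.id]
            assert (p.start, p.orientation) == (40 + 30 * i, "forward")

    def test_inverted_species_flagged_or_block_lost(self, rng):
        block = random_dna(rng, 20)
        s1 = GenomicSequence("s1", plant(random_dna(rng, 200), block, 50))
        s2 = GenomicSequence("s2", plant(random_dna(rng, 200), block, 90))
        s3 = GenomicSequence("s3", plant(random_dna(rng, 200), revcomp(block), 120))
        found = shared_identical_blocks([s1, s2, s3], 14, allow_inversion=True)
        assert len(found) == 1
        (p3,) = found[0].placements["s3"]
        assert (p3.start, p3.orientation) == (120, "inverted")
        assert shared_identical_blocks([s1, s2, s3], 14, allow_inversion=False) == []

    def test_placement_residues_match_block_seq(self, rng):
        block = random_dna(rng, 25)
        texts = {
            "a": plant(random_dna(rng, 150), block, 10),
            "b": plant(random_dna(rng, 150), revcomp(block), 60),
        }
        seqs = [GenomicSequence(k, v) for k, v in texts.items()]
        for b in shared_identical_blocks(seqs, 14):
            for sid, places in b.placements.items():
                for p in places:
                    segment = texts[sid][p.start:p.start + b.length]
                    expected = b.block_seq if p.orientation == "forward" else revcomp(b.block_seq)
                    assert segment == expected

    def test_single_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            shared_identical_blocks([GenomicSequence("s", random_dna(rng, 50))], 8)


class TestOracleEquivalence:
    @pytest.mark.parametrize("allow_inversion", [True, False])
    @pytest.mark.parametrize("n_seqs", [2, 3, 4])
    def test_random_with_planted_and_repeated_blocks(self, rng, n_seqs, allow_inversion):
        for trial in range(8):
            block = random_dna(rng, rng.integers(10, 26))
            texts = {}
            for i in range(n_seqs):
                bg = random_dna(rng, 150, with_n=0.02 if trial % 4 == 0 else 0.0)
                insert = revcomp(block) if (allow_inversion and i == n_seqs - 1
                                            and trial % 2) else block
                bg = plant(bg, insert, int(rng.integers(0, 150 - len(block))))
                if trial % 3 == 0:  # repeated block in one species
                    pos2 = int(rng.integers(0, 150 - len(block)))
                    bg = plant(bg, block, pos2)
                texts[f"s{i}"] = bg
            seqs = [GenomicSequence(k, v) for k, v in texts.items()]
            found = shared_identical_blocks(seqs, min_len=8,
                                            allow_inversion=allow_inversion)
            oracle = naive_shared_blocks(texts, 8, allow_inversion)
            assert canonical_blocks(found) == canonical_oracle(oracle)

    def test_pure_random_inputs_match_oracle_at_small_min_len(self, rng):
        for _ in range(5):
            texts = {f"s{i}": random_dna(rng, 120) for i in range(3)}
            seqs = [GenomicSequence(k, v) for k, v in texts.items()]
            found = shared_identical_blocks(seqs, min_len=5)
            assert canonical_blocks(found) == canonical_oracle(naive_shared_blocks(texts, 5, True))


class TestMonotonicity:
    def _planted_set(self, rng, n=4):
        block_a, block_b = random_dna(rng, 30), random_dna(rng, 16)
        seqs = []
        for i in range(n):
            bg = random_dna(rng, 300)
            bg = plant(bg, block_a, 20 + 10 * i)
            bg = plant(bg, block_b, 200 + 10 * i)
            seqs.append(GenomicSequence(f"s{i}", bg))
        return seqs

    def test_raising_min_len_never_adds_blocks(self, rng):
        seqs = self._planted_set(rng)
        low = {b.block_seq for b in shared_identical_blocks(seqs, 8)}
        high = {b.block_seq for b in shared_identical_blocks(seqs, 14)}
        # every high-threshold block is a (substring of a) low-threshold block
        for b in high:
            assert any(b in lb or revcomp(b) in lb for lb in low)
        assert len(high) <= len(low)

    def test_adding_a_sequence_never_adds_blocks(self, rng):
        seqs = self._planted_set(rng, n=4)
        subset = {b.block_seq for b in shared_identical_blocks(seqs[:3], 8)}
        full = {b.block_seq for b in shared_identical_blocks(seqs, 8)}
        for b in full:
            assert any(b in sb or revcomp(b) in sb for sb in subset)


class TestConnectors:
    def test_one_row_per_adjacent_pair(self, rng):
        block = random_dna(rng, 20)
        seqs = [GenomicSequence(f"s{i}", plant(random_dna(rng, 120), block, 30))
                for i in range(3)]
        found = shared_identical_blocks(seqs, 14)
        rows = blocks_to_connectors(found, ["s0", "s1", "s2"])
        assert len(rows) == 2
        assert not any(r["inverted"] for r in rows)

    def test_inverted_placement_flags_both_connectors(self, rng):
        block = random_dna(rng, 20)
        seqs = [
            GenomicSequence("s0", plant(random_dna(rng, 120), block, 30)),
            GenomicSequence("s1", plant(random_dna(rng, 120), revcomp(block), 40)),
            GenomicSequence("s2", plant(random_dna(rng, 120), block, 50)),
        ]
        found = shared_identical_blocks(seqs, 14)
        rows = blocks_to_connectors(found, ["s0", "s1", "s2"])
        assert [r["inverted"] for r in rows] == [True, True]

    def test_missing_species_errors_and_empty_blocks_ok(self, rng):
        assert blocks_to_connectors([], ["a", "b"]) == []
        block = random_dna(rng, 20)
        seqs = [GenomicSequence(f"s{i}", plant(random_dna(rng, 120), block, 30))
                for i in range(2)]
        found = shared_identical_blocks(seqs, 14)
        with pytest.raises(ValueError, match="missing"):
            blocks_to_connectors(found, ["s0", "nope"])
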