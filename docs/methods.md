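# Methods

## Scope and coordinates

The package analyses curated multi-species locus sets: genomic scaffolds
(FASTA) plus gene-feature annotations (BED6 with the name column encoding
`gene|feature_kind`). Ortholog identification itself is out of scope —
annotations are inputs. Coordinates are 0-based half-open everywhere
internally and in machine TSV columns; 1-based inclusive values appear only
in report columns suffixed `_1based`. Target sequences are restricted to
{A,C,G,T,N}; degenerate IUPAC codes are legal only in search patterns,
because the analysis scans genomic targets against degenerate queries and
never the reverse.

## Motif scanning

A pattern position matches a target base when the base is a member of the
position's IUPAC set; the mismatch count of a window is the number of
non-member positions, and a window is a hit when that count is within the
pattern's budget. Minus-strand hits are computed by scanning the plus
strand with the reverse-complemented pattern, which is exact:
`mismatches(P, revcomp(w)) == mismatches(revcomp(P), w)`.

**N policy.** A target N matches nothing (each N inside a window counts as
a mismatch). This is the conservative choice for masked assembly; a
`n-matches-n` policy is available that lets target N match pattern N only.
The historical desktop tools this emulates do not document their behaviour,
so the policy is explicit and configurable.

**Duplicates.** Overlapping hits and both-strand hits on the same footprint
(possible for near-palindromic patterns) are all reported by default —
faithful enumeration first. `dedup_footprint` keeps per (start, end) the
lower-mismatch hit, ties to '+'.

The scanner is vectorised (one boolean pass per pattern position over the
encoded sequence), so megabase-scale scans take well under a second. Its
correctness is pinned to a deliberately naive every-window oracle in the
test suite.

## Null model

The background control asks how often a *random* k-mer (with the same
mismatch budget) would hit. `random_kmers` draws i.i.d. k-mers;
`empirical_density` reports total hits, scanned bp and the mean spacing
("one instance every X bp"). The spacing denominator is single-strand bp
even when both strands are scanned — one figure per genomic bp — with a
`per_strand` option, since the convention behind published spacing figures
of this kind is usually unstated.

`expected_density_iid` is the analytic counterpart: the probability that a
random i.i.d. word lies in the pattern's Hamming ball, computed exactly by
a dynamic programme over positions and summed over strands. For a concrete
12-mer at budget 1 the ball has 1 + 12·3 = 37 words and the both-strand
density is 2·37/4¹² ≈ 4.41·10⁻⁶ per bp. Summing strands double-counts
words in the intersection of the forward and reverse balls; the
intersection is empty only for patterns ≥ 2(m+1) mismatches away from
their own reverse complement (the canonical 12-mer is exactly 2 away, so
its budget-1 balls share two words). The `dedup_union` option computes the
union probability by explicit ball enumeration instead; it is off by
default to match the plain per-strand scan.

## Shared identical blocks

Identity is exact — no gaps, no mismatches, N matches nothing — because
the analysis this supports draws *identical* sequence blocks. A candidate
block is a string (≥ `min_len`) present in every input, forward or
reverse-complemented when inversions are allowed. A candidate is suppressed
iff a single longer candidate covers every one of its occurrence intervals
in every sequence; this realises "contained within a longer block at the
same placements" while keeping a shorter string alive when it has an extra
standalone occurrence. Every candidate occurs in the first (reference)
sequence, so the finder enumerates the longest shared extension at each
reference position incrementally (the extension length can drop by at most
one per step) and takes substrings of those extensions as the candidate
pool; pruning then applies the coverage rule. Blocks are reported in
reference orientation with all placements per sequence, capped at 10 with
a warning (a drawn diagram connects one line per species; the cap and the
leftmost-placement convention for connectors are documented choices).

This is an O(n·scan) strategy adequate for locus-scale inputs (tens of kb);
whole-genome suffix-array engineering is explicitly out of scope. The test
suite pins the implementation to a full substring-enumeration oracle on
small inputs, including repeated and inverted plantings.

## Synteny classification

Rules apply in a fixed order per species: (1) pb and zen homeodomain exons
on one scaffold → `syntenic`, orientation from strand agreement; (2) on
separate scaffolds but the zen scaffold carries a pb-type YPWM exon within
`adjacency_window_bp` of a scaffold end → `likely_adjacent` (the split-
assembly signature); (3) every feature of a focal gene absent →
`gene_loss` with the genes listed; (4) otherwise `unresolved`.
Translocation is never called positively. `adjacency_window_bp` defaults
to 20 kb: the source heuristic says only "near one end", and 20 kb is small
against typical scaffold lengths while generous against exon placement
noise. Classification is invariant under scaffold relabeling and under
reverse-complementing a scaffold (coordinates and strands flipped), which
the suite checks.

`summarize_synteny` aggregates per pre-/post-divergence group (relative to
the Hox3/zen functional divergence) with explicit numerators and
denominators, so survey fractions like 3/66 stay exact.

## Ortholog grouping of motif instances

Hits are anchored to the nearest matching feature; the signed offset is
measured from the anchor's 5′ boundary in its reading orientation
(positive = downstream of the anchor). Flanks of `flank_len` (default
20 bp) either side are extracted in the *hit's* strand orientation so they
remain comparable across inverted loci; identity is ungapped, up-flanks
aligned at the motif-proximal edge, truncated flanks compared over the
overlap. Two instances are compatible when |Δoffset| ≤ `offset_tol_bp`
(default 2 000) and flank identity ≥ `min_flank_id` (default 0.6); groups
are connected components (single linkage, because conserved instances are
chained across progressively diverged clades), emitted when they span ≥ 2
species, numbered by leftmost mean offset. The thresholds are package
decisions, not reconstructions of any published criterion: 0.6 is far
above the 0.25 expected identity of random flanks yet reachable after
substantial neutral divergence, and 2 kb absorbs indel drift between
diverged species at locus scale.

## Construct design

`noncomp_transversion` maps A↔C and G↔T positionwise. This is the unique
base substitution that is simultaneously a transversion and never the
Watson–Crick complement, and it reproduces the printed TTAA→GGCC core-site
mutation; it is an involution with no fixed points (property-tested).
`tile_windows` is strict by default — the functional region is expected to
divide evenly into 47-nt windows (376 = 8·47); a lenient mode appends a
flagged partial window. `apply_edits` applies truncation, deletion,
transversion and substitution edits in base coordinates, rejects overlaps,
and requires substitution edits to state the expected original residues so
coordinate drift fails loudly rather than silently mutating the wrong
bases. The exact boundaries of the published construct series are only
available in supplementary material not bundled here, so the tiling
examples use a synthetic 1.4-kb enhancer with a 376-bp central region; the
anchored fact is the printed count of eight successive 47-nt windows.

## Synthetic data

The simulator states a world and the tests measure recovery in it:

- **Background**: one ancestral i.i.d. sequence per run (uniform base
  frequencies by default), each species diverged from it by independent
  point substitution at `per_base_divergence` (default 0.25 — two species
  then share ≈ 58% of background positions, deep enough that chance
  ≥14-bp shared blocks are effectively impossible). Substitution-only, no
  indels, so planted coordinates are exact across species by construction;
  this is what makes exact-boundary recovery a meaningful test, at the
  cost of realism (no rate heterogeneity, no indels, no phylogenetic
  correlation — a green recovery test says the algorithms are correct, not
  that real diverged genomes behave this way).
- **Blocks** are copied verbatim (reverse-complemented in designated
  species). Block edges are *sealed*: the single background position on
  each side is forced to differ between species. Without sealing, a
  flanking base survives divergence identically in all eight species in a
  substantial fraction of runs (≈ 0.75⁸ plus convergent substitutions per
  side) and the recovered block would legitimately overrun the planted
  boundary; sealing makes "recovered with exact boundaries" a property of
  the generator's world rather than a coin flip.
- **Motifs** are realized from the IUPAC pattern once per element, then
  per species mutated at exactly the requested number of positions to
  bases outside the pattern set — so planted mismatch counts are exact.
- **Genes, losses, splits**: features are annotations (background content
  beneath them is not specialised); losses omit a species' features;
  scaffold splits cut one scaffold in two and re-coordinate features, and
  a plant spanning a split is a config error.
- **Determinism**: one global seed; every element draws from its own
  `SeedSequence` substream, so adding a plant never perturbs the others,
  and outputs are byte-identical per seed.

The truth ledger records every planted element's realized sequence and
post-split coordinates (re-extraction from the emitted FASTA is tested),
plus each species' expected synteny class derived structurally from the
config.

## Numerical and degenerate-input conventions

Zero hits yield an undefined (None) spacing, not an error. A sequence
shorter than the pattern scans to an empty hit list. Hit ordering is
(start, strand) with '+' first; table rows sort by (seq_id, start, strand).
Palindromic blocks report forward placements only. The empirical-vs-
analytic density test uses a 3-binomial-SE band, ignoring the slight
negative covariance of overlapping windows (conservative at these
densities).

## Known limitations

Block finding is exact-identity only (no mismatched or gapped
conservation) and desk-scale by design. The synteny classifier sees only
the annotated focal features; partial gene models are treated as presence.
Ortholog grouping's single linkage can chain groups whose extreme members
violate the pairwise thresholds (the emitted `min_pairwise_flank_identity`
makes this visible). The analytic null assumes an i.i.d. background; no
GC-stratified or Markov background is provided.
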