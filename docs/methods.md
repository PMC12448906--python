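# Methods

This note records the model, the numerical and design choices, what the
synthetic data does and does not emulate, and the known limitations.

## Linear pangenome representation

The builder consumes a FASTA reference and a VCF of small variants.

* Ambiguous `N` bases are replaced by uniform random bases first
  (deterministic under the build seed), because `N` is not part of the index
  alphabet.
* **SNVs** are encoded in place: each site carries the IUPAC code of the
  union of its alleles. Multi-allelic sites merge; a site whose union would
  be all four bases is truncated to the reference plus the first two
  alternate alleles (logged), because the alphabet deliberately excludes the
  four-base code — keeping `Σ_poly` at 12 symbols keeps the Huffman tree
  small and a 16th code would match every read base, adding noise rather
  than signal. Records whose REF disagrees with the genome are dropped with
  a warning. SNVs are *not* re-applied inside INDEL fragment contexts;
  fragments copy the raw reference flanks.
* **INDELs** become padded fragments appended behind `#` separators, one
  `#` before each fragment. For an insertion at VCF position `p` (REF `X`,
  ALT `X·ins`): `ref[p−k+1..p] · ins · ref[p+1..p+k]`. For a deletion of `d`
  bases (REF `X·del`, ALT `X`): `ref[p−k+1..p] · ref[p+d+1..p+d+k]`.
  Context is truncated at chromosome edges, never an error. The context
  length `k` defaults to 101 — the simulated read length — so any read
  overlapping the allele fits entirely inside its fragment. INDELs longer
  than 50 bp are skipped (the representation targets common small
  variants); duplicate INDEL records: first wins.
* **Ann** stores, per fragment, the chromosome, the VCF anchor position, the
  left-context length and the inserted/deleted lengths; backbone spans map
  by offset. Projection of a position inside an inserted allele reports the
  last reference base before the insertion; positions after the allele (or
  after a deleted span) shift by the length difference. A deletion
  fragment's anchor is its first left-context base. Separator positions
  have no biological coordinate and projecting them raises.

All VCF positions are 1-based; internal text coordinates are 0-based
half-open. The production text is `T · revcomp(T) · $` with a single
sentinel; the worked-example mode indexes a bare symbol string without the
reverse-complement half, which is how the published example strings are
reproduced.

## Index structures

* **Symbol order** `$ < # < A < B < C < D < G < H < K < M < R < S < T < V <
  W < Y` (sentinels first, letters alphabetical). The order is validated by
  reproducing the published worked-example BWT byte for byte; it is
  serialized with the index and checked on load.
* **Suffix array** by prefix doubling over numpy lexsort — O(n log n) with
  vectorised passes, entirely adequate at the hundreds-of-kilobase scale
  this package targets. BWT as `W[i] = text[(SA[i]−1) mod n]`.
* **Split wavelet trees.** `U[i] = 1` iff `W[i] ∈ Σ_poly`; `Wl` (balanced
  tree over 4 symbols, depth 2) and `Wr` (Huffman-shaped over 12 symbols,
  frequent symbols near the root; ties broken by symbol order so the shape
  is canonical). Both trees are built over the full sub-alphabet even when
  symbols are absent, so every code has a leaf and absent symbols count
  zero.
* **Rank support**: bits packed into 64-bit words with three checkpoint
  levels — absolute counts per 2^16-bit superblock, block-relative counts
  per 512-bit block, block-relative counts per word — so a rank is three
  lookups plus one masked popcount, and queries vectorise over position
  arrays.
* **Occ batching.** `Occ_ϕ(W,i)` for a symbol set ϕ routes the U rank once,
  then descends each wavelet tree visiting every shared node once for the
  whole batch (and for a whole array of positions at once). The
  instrumented rank-call count is asserted in tests to never exceed the
  per-symbol total.
* **Occ convention** is inclusive of position `i`; boundary `i = −1` returns
  0. Backward search therefore uses `Occ(l−1)` / `Occ(r)` on inclusive
  interval ends, implemented in exclusive-prefix form internally.
* **Sampled SA** with step `d = 8` by default (text-position sampling:
  rows whose suffix position is ≡ 0 mod d are marked). `locate` LF-walks to
  the nearest mark; `extract` starts from an inverse-SA sample past the end
  of the requested span and LF-walks down, reconstructing the substring
  from the index itself rather than from any stored plain text. The spans
  extracted this way are the aligner's candidate windows, which keeps the
  aligner's memory at the index size.
* **Serialization**: a single container file, magic `PANALN-LITE`, version
  number, JSON section table, raw little-endian arrays. Only the BWT,
  the SA/ISA samples, Ann and metadata are stored; U, both wavelet trees
  and C are rebuilt deterministically on load, and the stored Huffman code
  lengths are cross-checked against the rebuilt tree. Wrong magic, wrong
  version and truncation each raise a format error.

### Compiled inner loops

The interval-stepping, D-array, LF-walk and extraction loops are also
implemented as numba kernels over a flattened view of the same structures
(`_kernels.py`). The class-based structures remain the canonical
implementation behind the public `occ_c` / `occ_batch` / `lf` API; the
kernels are differentially tested against them, and both against naive
scans. First use JITs for a few seconds; compiled artifacts are cached.

## Queries

A DNA pattern can be compatible with several distinct strings in the text,
so backward search carries a set `S` of SA intervals, mapping each interval
through every symbol of `Γγ` per step. Result intervals are pairwise
disjoint by construction; normalization sorts and fuses touching ones.
`S` is capped at 64 intervals — the widest are kept, the set is flagged
truncated, a truncated count is reported as a lower bound, and the aligner
treats such seeds as repetitive (MAPQ 0). A read base `N` matches nothing
and empties the set, which is exactly how it should register as a
difference in the D array. `locate` reflects hits in the reverse-complement
half to forward coordinates (`pos_fwd = |T| − pos − |P|`, strand `−`),
discards spans crossing `#`/chromosome boundaries, projects through Ann,
and returns deduplicated hits sorted by (chrom, pos, strand).

## Seeding

`D[i]` is computed incrementally: appending a base on the right of the
growing substring is implemented as prepending its complement to the
tracked reverse-complement pattern, so one backward step per base suffices
(the index holds both strands, making the two directions equivalent — the
strand-symmetry of `count` is asserted in tests). On failure the counter
increments and the next substring starts at the following position, so the
whole array costs O(|R|) steps.

Cut semantics: a discontinuity at `i` cuts between `i` and `i+1`. `K2`
positions come from the reversed D2 array and are already in read
coordinates; no further reflection. The LEOF is the longest fragment,
leftmost on ties. If a seed has zero occurrences (possible because the two
D arrays contribute independent boundaries), the aligner falls back to the
next-longest EOF; a read whose every EOF is hitless is reported unmapped.
Seeds shorter than 19 bp are still attempted but the record's MAPQ is
capped at 20 — below typical confident-call thresholds but not discarded,
since no minimum seed length is inherent to the partition.

## Extension and reporting

Candidate windows span the predicted read placement plus a margin of
`max(16, ⌈0.1·|R|⌉)` on each side (enough for the 50-bp INDEL cap never to
be reached in practice at 101-bp reads, and cheap), clipped at the Ann
record containing the seed hit so windows never cross `#`, `$` or a
chromosome boundary.

The wavefront aligner minimises gap-affine cost (mismatch `x = 4`, gap open
`o = 6`, gap extend `e = 2`; a length-L gap costs `o + L·e`) with the
furthest-reaching extension using the `Γγ` inclusive match. Two modes:
global, which is the `wfa_align` contract and what the DP oracle tests pin,
and *text-ends-free*, which the aligner uses so the margin flanks are not
charged — aligning the read end-to-end against a margin-padded window under
a strictly global objective would add an identical ~`o + 2·margin·e`
penalty to every candidate and inflate the O(ns) runtime for no ranking
benefit. Both modes are verified against the same Gotoh oracle. A
zero-cost fast path checks the read against the window at the exact
predicted offset before invoking the wavefront machinery; candidates
costing more than 80 are dropped as hopeless (an alignment worth reporting
at 101 bp sits far below: ten mismatches cost 40).

The cheapest candidate (ties: smallest chromosome, position, strand) is the
primary record. `MAPQ = min(60, 6·(s₂ − s₁))` with `s₂` the runner-up cost
at a *different* locus (no runner-up → 60); repetitive seeds force MAPQ 0.
This formula is a declared heuristic, not derived from a probability model.
SAM output is v1.6 text with `@HD`/`@SQ`/`@PG` headers, flags 0/16/4, and
the alignment cost negated in `AS`. Unmapped is a result, never an error.
Paired input files are aligned independently; only the pairing flags are
set. No soft clipping: the CIGAR consumes the whole read.

## Synthetic data

The generator emulates the standard short-read benchmarking design: a
uniform random reference (default 100 kb, one chromosome), 1,000 SNVs at
distinct sites and 100 INDELs of 1–10 bp placed without overlaps and away
from chromosome edges, written as a spec-conforming VCF; 10,000 101-bp
reads drawn uniformly from both strands, carrying each overlapped variant
allele with probability 0.5 (diploid-like) and acquiring i.i.d.
substitution errors at 0.2% per base. Errors-only and variants-only
regimes fall out by zeroing the other rate. Everything is deterministic
given the seed (integer RNG streams only).

What it does **not** emulate: base-quality profiles, indel sequencing
errors, coverage or GC bias, repeat structure of real genomes, linked
(haplotype-phased) variants. Consequently the headline desk-scale ratios —
100% mapped, ≈100% correctly mapped on this generator — sit above what the
same method achieves on a human pangenome, where repetitive sequence and
dense variation create genuinely ambiguous placements; the tests
demonstrate correctness of the machinery, not field accuracy. Scoring uses
the standard criterion: a read is correctly mapped when the primary
alignment is on the truth chromosome and overlaps the simulator-recorded
origin span by at least 90% of the read length.

Problem sizes used by the test suite and the acceptance script — 100-kb
genome, 10,000 reads, plus oracle sweeps over hundreds of kilobase-scale
random texts — were chosen as the largest sizes that keep a full run
comfortable on a single workstation core.

## Numerical and degenerate-input choices

* Rank/occ boundary: position −1 (empty prefix) returns 0 everywhere.
* Empty pattern: `count` returns the full-text interval; zero occurrences
  is an empty set, not an error.
* `extract` of length 0 is the empty string; spans touching the terminal
  sentinel are served by a special case (the sentinel is always the last
  symbol).
* Huffman ties are broken by symbol order; the balanced tree splits the
  sorted alphabet `⌈σ/2⌉`/`⌊σ/2⌋`.
* WFA traceback picks gap-closing provenance before mismatch on cost ties,
  which is cosmetic: any choice is an optimal alignment and only the score
  is contract.
* The suffix-array builder requires exactly one sentinel, last; the
  wavelet trees reject symbols outside their alphabet; deserialization
  fails closed on any structural mismatch.

## Limitations

* Pure-Python + numba: index construction is O(n log n) with comfortable
  constants to a few megabases, not engineered for human-genome scale.
* Single-end logic only; no proper-pair rescue or insert-size model.
* No soft clipping, secondary alignments, or base-quality-aware scoring.
* Long reads would need chaining across multiple seeds; the single-LEOF
  strategy degrades as read length and error count grow.
* The 64-interval cap makes counts of highly repetitive patterns lower
  bounds; exact counting of such patterns is not a goal of the aligner
  path.
* Because fragments copy raw reference context, a read that carries an
  INDEL allele *and* a nearby SNV alternate allele has no exact match
  anywhere in the text; it still aligns at its origin, paying one mismatch.
  Jointly-encoded alleles would require haplotype-aware fragments, which
  are out of scope.
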