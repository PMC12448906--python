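# panaln

Pangenome indexing and short-read alignment over a *linear* pangenome
representation: a reference genome plus a VCF of small variants is flattened
into a single symbol string, indexed with a split wavelet-tree FM-index, and
queried with an IUPAC-compatible backward search. Reads are seeded with a
variable-length fragment derived from paired D arrays and extended with an
IUPAC-aware gap-affine wavefront aligner that emits SAM.

## Why

Aligning reads against a single reference genome penalises every read that
carries a known population variant (reference bias). Graph pangenome indexes
remove that bias but their suffix-sorting blows up combinatorially with the
number of encoded variants. The linear representation sidesteps the blowup:

* **SNPs** are folded into the backbone in place — a site with alleles A/T
  becomes the IUPAC code `W`, so the text stays the same length and a read
  spelling either allele matches at zero cost;
* **INDELs** become *padded fragments*: the alternate allele flanked by up to
  `k` bases of reference context (`k` defaults to the read length), appended
  after the backbone behind `#` separators. A read overlapping the indel
  allele matches exactly inside its fragment, and an annotation table `Ann`
  projects fragment coordinates back to the chromosome.

The indexed text is `T · reverse_complement(T) · $`, so both strands are
searched in one pass.

## The index

Let `W` be the BWT of the text over the alphabet
`Σ = Σ_uniq ∪ Σ_poly`, with `Σ_uniq = {A,C,G,T}` and
`Σ_poly = {K,S,B,Y,M,H,V,R,D,W,#,$}`. A bitvector `U` marks BWT positions
holding polymorphic symbols; the `Σ_uniq` subsequence `Wl` goes into a
balanced wavelet tree and the (much shorter, skewed) `Σ_poly` subsequence
`Wr` into a Huffman-shaped one. An `Occ_c(W,i)` query routes through
`rank1(U,i)` and descends one tree; backward search uses the classic step

    l(cP) = C[c] + Occ_c(W, l(P) − 1),   r(cP) = C[c] + Occ_c(W, r(P)) − 1

but generalised: a read base `γ` is compatible with every symbol in
`Γγ = { s : γ ∈ bases(s) }` (e.g. `Γ_A = {M,H,V,R,D,W,A}`), so each step maps
an interval **set** through all compatible symbols, batching the shared
wavelet-tree rank queries (`Occ_ϕ`) across the symbol set and interval
boundaries. `count`, `locate` (via a sampled suffix array) and `extract`
(substring reconstruction from the index itself, no plain-text copy) are
built on this step.

## Seeding and extension

For a read `R`, `D[i]` is a lower bound on the number of differences between
`R[0..i]` and any compatible region: it increments each time the growing
substring stops occurring. Discontinuities of `D` lag the true difference
(the *delay phenomenon*), so a second D array computed on the reverse
complement brackets each difference from the other side. Cutting `R` at the
merged discontinuity sets `K1 ∪ K2` yields the *equal overlapping fragments*
(EOFs); the longest one (LEOF) is the seed. Seed hits are located, a
margin-padded window is extracted around each, and the read is aligned to
every window with a wavefront aligner whose extend step replaces character
equality by the `Γγ` compatibility test (gap-affine costs, default
mismatch 4, gap open 6, gap extend 2). The cheapest candidate becomes the
primary SAM record; MAPQ reflects the cost gap to the runner-up.

## Worked example

`python examples/build_and_query.py` builds a 36-bp toy pangenome with two
SNPs and one insertion and prints:

```
linear representation T (51 symbols): CCCTWACCCTAACCCYTAACGGATTACAGGATTACA#ACGGATGGTACAGG
count('TAA') = 7 compatible occurrences; forward hits at [('chr1', 4), ('chr1', 10), ('chr1', 17)]
count('TTA') = 7 compatible occurrences; forward hits at [('chr1', 4), ('chr1', 16), ('chr1', 24), ('chr1', 32)]
insertion-allele pattern 'GATGGTAC': hit inside fragment, projected to chr1:22
extract(0, 20) = 'CCCTWACCCTAACCCYTAAC'  (the first 20 backbone symbols)
```

`TAA` and `TTA` both hit position 4 — the `W` at offset 5 absorbs the A/T
alleles — and a pattern spelling the inserted `GG` allele is found inside the
padded fragment and projected back to its chromosome coordinate. Counts
cover both strands. The other examples show the D-array seed partition
(`examples/seed_partition.py`) and a miniature end-to-end benchmark
(`examples/align_simulated.py`).

As a shell tool:

```sh
panaln simulate -o sim                    # FASTA + VCF + FASTQ + truth TSV
panaln index -r sim.fa -v sim.vcf -o pan  # build pan.pidx
panaln align -x pan -q sim.fq -o out.sam --truth sim.truth.tsv
panaln seed -x pan --read ACGT... --debug # inspect D arrays / EOFs
```

## Scope

Single-end short reads are the tested path (paired files are aligned
independently with mate flags from pairing only). Structural variants,
haplotype-aware indexing, long-read chaining and BAM/CRAM output are out of
scope.
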