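"""Build a tiny pangenome from a reference + variants and run the three
fundamental queries: count, locate, extract.

The reference carries two SNPs (encoded in place as IUPAC codes) and one
insertion (appended as a context-padded fragment after a '#' separator), so
a pattern spelling either allele finds the same locus.
"""

from panaln import PanalnIndex, ReferenceGenome, VariantSet, build_pangenome
from panaln.queries import count, extract, locate

ref = ReferenceGenome([("chr1", "CCCTAACCCTAACCCTTAACGGATTACAGGATTACA")])
variants = VariantSet(
    snvs=[("chr1", 5, "A", ("T",)),      # A/T -> W
          ("chr1", 16, "T", ("C",))],    # T/C -> Y
    indels=[("chr1", 24, "T", "TGG")],   # GG inserted after position 24
)

pg = build_pangenome(ref, variants, context_k=6)
index = PanalnIndex.build(pg)
print(f"linear representation T ({len(pg.T)} symbols): {pg.T}")

# 'TAA' also matches 'TWA': the IUPAC symbol absorbs both alleles
for pattern in ("TAA", "TTA"):
    iv = count(index, pattern)
    hits = locate(index, iv, len(pattern))
    print(f"count({pattern!r}) = {iv.width} compatible occurrences; "
          f"forward hits at "
          f"{[(h.chrom, h.pos) for h in hits if h.strand == '+']}")

# a pattern containing the inserted allele exists only in the padded fragment
pat = "GATGGTAC"  # spans the GG insertion
hits = locate(index, count(index, pat), len(pat))
h = next(h for h in hits if h.inside_indel)
print(f"insertion-allele pattern {pat!r}: hit inside fragment, "
      f"projected to {h.chrom}:{h.pos}")

# extract reconstructs any slice of T from the index itself
print(f"extract(0, 20) = {extract(index, 0, 20)!r}  "
      "(the first 20 backbone symbols)")
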