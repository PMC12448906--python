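"""Show how the paired D arrays cut a read into equal overlapping fragments.

A 100-bp read is drawn from a 100-kb synthetic genome and three substitution
errors are planted.  D1 (left-to-right) notices each error only at or after
its position (the delay phenomenon); D2, computed on the reverse complement
and reversed, brackets it from the other side.  Cutting at the merged
discontinuities yields fragments that avoid the errors; the longest (LEOF)
is the alignment seed.
"""

from panaln import PanalnIndex, ReferenceGenome, VariantSet, build_pangenome
from panaln.queries import count
from panaln.seeding import find_leof
from panaln.simulate import SimConfig, simulate_genome

cfg = SimConfig(genome_length=100_000, snv_count=0, indel_count=0, seed=1)
ref, _ = simulate_genome(cfg)
index = PanalnIndex.build(build_pangenome(ref, VariantSet(), context_k=101))

MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}
errors = (19, 30, 93)
read = list(ref.chroms[0][1][20_000:20_100])
for e in errors:
    read[e] = MUT[read[e]]
read = "".join(read)

part = find_leof(index, read)
print(f"planted errors at offsets {errors}")
print(f"K1 (D1 discontinuities):  {part.k1.tolist()}")
print(f"K2 (D2' discontinuities): {part.k2.tolist()}")
print(f"{len(part.fragments)} equal overlapping fragments: {part.fragments}")
s, e = part.leof
print(f"LEOF = read[{s}:{e}], length {e - s}, "
      f"{count(index, read[s:e]).width} occurrence(s) in the index")
print("an error inside the LEOF would have broken the seed; here it is "
      f"error-free: {not any(s <= x < e for x in errors)}")
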