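"""Linear representation: SNP encoding, INDEL padding, assembly, projection."""

import logging

import numpy as np
import pytest

from panaln.iupac import TABLES
from panaln.pangenome import (
    AnnotationTable,
    ReferenceGenome,
    VariantSet,
    assemble_text,
    build_indel_fragments,
    build_pangenome,
    encode_snps,
    project_position,
    randomize_ambiguous,
    reverse_complement,
)

# reference consistent with the published example backbone: the SNVs A/T at
# position 5 and T/C at position 16 turn it into CCCTWACCCTAACCCYTAAC
EXAMPLE_REF = "CCCTAACCCTAACCCTTAAC"
EXAMPLE_BACKBONE = "CCCTWACCCTAACCCYTAAC"


def _ref(seq="ACCCTAACCCTAACCCTTAAGG", name="chr1"):
    return ReferenceGenome([(name, seq)])


class TestEncodeSnps:
    def test_published_backbone(self):
        vs = VariantSet(snvs=[("chr1", 5, "A", ("T",)),
                              ("chr1", 16, "T", ("C",))])
        assert encode_snps(_ref(EXAMPLE_REF), vs) == EXAMPLE_BACKBONE

    def test_no_variants_is_identity(self):
        assert encode_snps(_ref(), VariantSet()) == _ref().chroms[0][1]

    def test_multiallelic_merges_to_three_base_code(self):
        vs = VariantSet(snvs=[("chr1", 1, "A", ("C",)),
                              ("chr1", 1, "A", ("G",))])
        out = encode_snps(_ref("AAAA"), vs)
        assert out[0] == TABLES.code_of_baseset[frozenset("ACG")] == "V"

    def test_ref_mismatch_rejected_with_warning(self, caplog):
        vs = VariantSet(snvs=[("chr1", 1, "G", ("T",))])
        with caplog.at_level(logging.WARNING):
            out = encode_snps(_ref("AAAA"), vs)
        assert out == "AAAA"
        assert "does not match" in caplog.text

    def test_four_base_union_truncated(self, caplog):
        vs = VariantSet(snvs=[("chr1", 1, "A", ("C", "G", "T"))])
        with caplog.at_level(logging.WARNING):
            out = encode_snps(_ref("AAAA"), vs)
        assert out[0] == "V"  # ref A + first two alts C,G
        assert "four bases" in caplog.text


class TestIndelFragments:
    def test_insertion_padding_arithmetic(self):
        # T inserted after position 8 of a 16-bp chromosome, k=4
        seq = "GATTACAGCTGATCGA"
        vs = VariantSet(indels=[("chr1", 8, seq[7], seq[7] + "T")])
        frags, recs = build_indel_fragments(_ref(seq), vs, context_k=4)
        assert frags == [seq[4:8] + "T" + seq[8:12]]
        assert recs[0].anchor_pos == 5
        assert (recs[0].left_len, recs[0].mid_len, recs[0].del_len) == (4, 1, 0)

    def test_deletion_splice(self):
        # delete 2 bases after position 6, k=3: 3 left + 3 right = length 6
        seq = "ACGTACGTACGTACGT"
        vs = VariantSet(indels=[("chr1", 6, seq[5:8], seq[5])])
        frags, _ = build_indel_fragments(_ref(seq), vs, context_k=3)
        assert frags == [seq[3:6] + seq[8:11]]
        assert len(frags[0]) == 6

    def test_context_zero_rejected(self):
        with pytest.raises(ValueError, match="context_k"):
            build_indel_fragments(_ref(), VariantSet(), context_k=0)

    def test_edge_truncation_not_error(self):
        seq = "ACGTACGT"
        vs = VariantSet(indels=[("chr1", 1, "A", "ATT")])
        frags, recs = build_indel_fragments(_ref(seq), vs, context_k=5)
        assert frags == ["A" + "TT" + seq[1:6]]  # left context truncated to 1
        assert recs[0].anchor_pos == 1

    def test_duplicate_indel_first_wins(self, caplog):
        seq = "ACGTACGTACGT"
        vs = VariantSet(indels=[("chr1", 5, seq[4], seq[4] + "AA"),
                                ("chr1", 5, seq[4], seq[4] + "CC")])
        with caplog.at_level(logging.WARNING):
            frags, _ = build_indel_fragments(_ref(seq), vs, context_k=2)
        assert len(frags) == 1
        assert "AA" in frags[0]

    def test_overlong_indel_skipped(self, caplog):
        seq = "A" * 200
        vs = VariantSet(indels=[("chr1", 50, "A", "A" + "C" * 60)])
        with caplog.at_level(logging.WARNING):
            frags, _ = build_indel_fragments(_ref(seq), vs, context_k=4)
        assert frags == []
        assert "longer than" in caplog.text


class TestAssemble:
    def test_zero_fragments(self):
        assert assemble_text("ACGT", []) == "ACGT"

    def test_separator_layout(self):
        t = assemble_text("ACGT", ["AA", "CC", "GG"])
        assert t == "ACGT#AA#CC#GG"
        assert t.count("#") == 3

    def test_fragment_with_separator_rejected(self):
        with pytest.raises(ValueError):
            assemble_text("ACGT", ["A#A"])


class TestReverseComplement:
    @pytest.mark.parametrize("s,expected", [
        ("W", "W"), ("ACGT", "ACGT"), ("KMY", "RKM"), ("#", "#"),
        ("AC#GT", "AC#GT"),
    ])
    def test_examples(self, s, expected):
        assert reverse_complement(s) == expected

    def test_involution(self):
        s = "ACGTWKYRMSBDHV#"
        assert reverse_complement(reverse_complement(s)) == s

    def test_sentinel_rejected(self):
        with pytest.raises(ValueError):
            reverse_complement("ACG$")


class TestRandomizeAmbiguous:
    def test_deterministic_and_resolved(self):
        ref = _ref("ANANNA")
        a = randomize_ambiguous(ref, seed=9).chroms[0][1]
        b = randomize_ambiguous(ref, seed=9).chroms[0][1]
        assert a == b and "N" not in a
        assert a[0] == "A" and a[2] == "A" and a[5] == "A"

    def test_no_n_unchanged(self):
        ref = _ref("ACGTACGT")
        assert randomize_ambiguous(ref, seed=0).chroms[0][1] == "ACGTACGT"

    def test_base_frequencies_uniform(self):
        ref = _ref("N" * 10_000)
        out = randomize_ambiguous(ref, seed=5).chroms[0][1]
        # each base within 3 sigma of 2500 (binomial sd ~ 43.3)
        for b in "ACGT":
            assert abs(out.count(b) - 2500) < 3 * 43.4


class TestProjection:
    def test_backbone_and_fragments(self, small_pangenome):
        ref, vs, pg = small_pangenome
        ann = pg.ann
        assert project_position(ann, 0) == ("chr1", 1, False)
        frag = next(r for r in ann.records if r.variant_kind == "insertion")
        chrom, pos, inside = project_position(ann, frag.text_start)
        assert inside and pos == frag.anchor_pos
        # first base after the insertion's left context + allele resumes
        off = frag.left_len + frag.mid_len
        _, pos2, _ = project_position(ann, frag.text_start + off)
        assert pos2 == frag.vcf_pos + 1

    def test_deletion_projection_skips_deleted_span(self, small_pangenome):
        _, _, pg = small_pangenome
        frag = next(r for r in pg.ann.records if r.variant_kind == "deletion")
        _, pos, _ = project_position(pg.ann, frag.text_start + frag.left_len)
        assert pos == frag.vcf_pos + frag.del_len + 1

    def test_separator_has_no_coordinate(self, small_pangenome):
        _, _, pg = small_pangenome
        frag = next(r for r in pg.ann.records if r.kind != 0)
        with pytest.raises(ValueError):
            project_position(pg.ann, frag.text_start - 1)  # the '#'

    def test_ann_covers_text(self, small_pangenome):
        _, _, pg = small_pangenome
        spans = sum(r.text_end - r.text_start for r in pg.ann.records)
        n_sep = pg.T.count("#")
        assert spans + n_sep == len(pg.T)
        # projection is total away from separators
        for p in range(0, len(pg.T), 997):
            if pg.T[p] != "#":
                project_position(pg.ann, p)


class TestRoundTrip:
    def test_backbone_decodes_back_to_reference(self, small_pangenome):
        ref, vs, pg = small_pangenome
        seq = ref.chroms[0][1]
        backbone = pg.T[: len(seq)]
        for (chrom, pos, rbase, alts) in vs.snvs:
            alleles = TABLES.baseset_of_code[backbone[pos - 1]]
            assert rbase in alleles
            assert set(alts) <= alleles
        # non-variant positions untouched
        snv_pos = {p for _, p, _, _ in vs.snvs}
        same = [i for i in range(len(seq)) if i + 1 not in snv_pos]
        assert all(backbone[i] == seq[i] for i in same[:2000])
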