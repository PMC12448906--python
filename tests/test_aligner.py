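"""End-to-end read alignment: windows, candidate ranking, SAM emission."""

import io
import random

import pysam
import pytest

from conftest import random_genome
from panaln.aligner import (
    AlignParams,
    align_read,
    make_windows,
    write_sam,
)
from panaln.fmindex import PanalnIndex
from panaln.pangenome import ReferenceGenome, VariantSet, build_pangenome
from panaln.queries import count, locate
from panaln.seeding import revcomp_read

MUT = {"A": "C", "C": "G", "G": "T", "T": "A"}


class TestAlignRead:
    def test_error_free_read_maps_to_origin(self, plain_index):
        seq, idx = plain_index
        rec = align_read(idx, "r1", seq[4321:4422])[0]
        assert (rec.chrom, rec.pos, rec.score) == ("chr1", 4322, 0)
        assert rec.cigar == "101M"
        assert rec.flag == 0
        assert rec.mapq == 60

    def test_reverse_strand_read(self, plain_index):
        seq, idx = plain_index
        rec = align_read(idx, "r1", revcomp_read(seq[4321:4422]))[0]
        assert (rec.chrom, rec.pos) == ("chr1", 4322)
        assert rec.flag == 16

    def test_read_with_errors_still_at_origin(self, plain_index):
        seq, idx = plain_index
        read = list(seq[8000:8101])
        for p in (15, 55, 90):
            read[p] = MUT[read[p]]
        rec = align_read(idx, "r1", "".join(read))[0]
        assert (rec.chrom, rec.pos) == ("chr1", 8001)
        assert rec.score == 3 * AlignParams().penalties.mismatch

    def test_alt_allele_read_scores_zero(self, small_pangenome, small_index):
        """A read carrying a known SNV alt matches the IUPAC backbone at no
        cost: the pangenome removes the reference bias."""
        ref, vs, _ = small_pangenome
        chrom, pos, rbase, alts = vs.snvs[0]
        seq = ref.chroms[0][1]
        read = list(seq[pos - 51: pos + 50])
        assert read[50] == rbase
        read[50] = alts[0]
        rec = align_read(small_index, "alt", "".join(read))[0]
        assert (rec.chrom, rec.pos, rec.score) == (chrom, pos - 50, 0)

    def test_insertion_allele_read_maps_inside_fragment(self, small_pangenome,
                                                        small_index):
        ref, vs, _ = small_pangenome
        chrom, pos, rall, aall = vs.indels[0]  # the insertion
        seq = ref.chroms[0][1]
        ins = aall[1:]
        # 50 bases before the anchor, the allele, then reference after
        read = seq[pos - 50: pos] + ins + seq[pos: pos + 51 - len(ins)]
        rec = align_read(small_index, "ins", read)[0]
        assert rec.score == 0
        assert rec.chrom == chrom
        assert abs(rec.pos - (pos - 49)) <= 1

    def test_unalignable_read_reported_unmapped(self, plain_index):
        _, idx = plain_index
        rec = align_read(idx, "nn", "N" * 101)[0]
        assert rec.is_unmapped

    def test_ambiguous_read_gets_low_mapq(self):
        # a genome whose left and right halves repeat a 300-bp block
        block = random_genome(300, seed=5)
        seq = block + random_genome(400, seed=6) + block
        pg = build_pangenome(ReferenceGenome([("c", seq)]), VariantSet(),
                             context_k=50)
        idx = PanalnIndex.build(pg)
        rec = align_read(idx, "amb", block[100:201])[0]
        assert not rec.is_unmapped
        assert rec.mapq == 0  # two equally good loci

    def test_deletion_allele_read(self, small_pangenome, small_index):
        ref, vs, _ = small_pangenome
        chrom, pos, rall, aall = vs.indels[1]  # the deletion
        seq = ref.chroms[0][1]
        dl = len(rall) - 1
        read = seq[pos - 50: pos] + seq[pos + dl: pos + dl + 51]
        rec = align_read(small_index, "del", read)[0]
        assert rec.score == 0
        assert abs(rec.pos - (pos - 49)) <= 1


class TestRecovery:
    def test_error_free_variant_reads_recovered(self, tmp_path):
        """Variants-only regime: with no sequencing errors the search
        reduces to exact matching and nearly every read must land on its
        origin under the 90%-overlap rule."""
        from panaln.simulate import (SimConfig, score_alignments,
                                     simulate_genome, simulate_reads)
        cfg = SimConfig(genome_length=30_000, snv_count=300, indel_count=30,
                        read_count=400, error_rate=0.0, seed=13)
        ref, vs = simulate_genome(cfg)
        pg = build_pangenome(ref, vs, context_k=cfg.read_length)
        idx = PanalnIndex.build(pg)
        reads, truth = simulate_reads(ref, vs, cfg)
        recs = [align_read(idx, rid, s)[0] for rid, s in reads]
        sam = str(tmp_path / "sim_s.sam")
        write_sam(recs, idx, sam)
        m = score_alignments(sam, truth)
        assert m["correct_ratio"] >= 0.99
        # nearly all error-free reads align at zero cost; the exceptions
        # carry an INDEL allele plus a nearby SNV alt, which no single
        # fragment represents jointly (fragments copy raw reference context)
        zero = sum(r.score == 0 for r in recs if not r.is_unmapped)
        assert zero / len(recs) >= 0.95


class TestMakeWindows:
    def test_window_centred_with_margin(self, plain_index):
        seq, idx = plain_index
        pat = seq[5000:5020]
        hits = locate(idx, count(idx, pat), 20)
        params = AlignParams()
        wins = make_windows(idx, [h for h in hits if h.strand == "+"],
                            read_len=101, seed_start=0, seed_len=20,
                            params=params)
        assert len(wins) == 1
        w = wins[0]
        assert w.text_start == 5000 - params.margin(101)
        assert w.length == 101 + 2 * params.margin(101)

    def test_window_clipped_at_chromosome_start(self, plain_index):
        seq, idx = plain_index
        pat = seq[0:25]
        hits = [h for h in locate(idx, count(idx, pat), 25) if h.strand == "+"]
        wins = make_windows(idx, hits, 101, 0, 25, AlignParams())
        assert wins[0].text_start == 0

    def test_window_inside_fragment_clipped_at_separator(self, small_pangenome,
                                                         small_index):
        _, _, pg = small_pangenome
        frag = next(r for r in pg.ann.records if r.variant_kind == "insertion")
        mid = frag.text_start + frag.left_len
        pat = pg.T[mid - 4: mid + 8]
        hits = [h for h in locate(small_index, count(small_index, pat), len(pat))
                if h.inside_indel and h.strand == "+"]
        wins = make_windows(small_index, hits, 101, 0, len(pat), AlignParams())
        for w in wins:
            assert w.text_start >= frag.text_start
            assert w.text_start + w.length <= frag.text_end


class TestWriteSam:
    def _records(self, idx, seq, n=3):
        out = []
        for i in range(n):
            p = 1000 * (i + 1)
            out.append(align_read(idx, f"r{i}", seq[p: p + 101])[0])
        return out

    def test_header_only_for_zero_reads(self, plain_index, tmp_path):
        _, idx = plain_index
        p = tmp_path / "empty.sam"
        write_sam([], idx, str(p))
        lines = p.read_text().splitlines()
        assert all(l.startswith("@") for l in lines)
        assert any(l.startswith("@SQ") and "SN:chr1" in l for l in lines)

    def test_round_trips_through_pysam(self, plain_index, tmp_path):
        seq, idx = plain_index
        recs = self._records(idx, seq)
        recs.append(align_read(idx, "unm", "N" * 101)[0])
        path = str(tmp_path / "out.sam")
        write_sam(recs, idx, path)
        with pysam.AlignmentFile(path, "r") as sam:
            assert sam.header["SQ"][0]["SN"] == "chr1"
            got = list(sam)
        assert len(got) == 4
        for i, rec in enumerate(got[:3]):
            assert rec.reference_start + 1 == recs[i].pos
            assert rec.cigarstring == "101M"
            assert rec.get_tag("AS") == 0
            assert not rec.is_unmapped
            assert rec.query_sequence == recs[i].seq
        assert got[3].is_unmapped

    def test_cigar_consumes_read(self, plain_index, tmp_path):
        seq, idx = plain_index
        read = list(seq[3000:3101])
        read[50] = MUT[read[50]]
        rec = align_read(idx, "x", "".join(read))[0]
        path = str(tmp_path / "one.sam")
        write_sam([rec], idx, path)
        with pysam.AlignmentFile(path, "r") as sam:
            r = next(iter(sam))
            assert r.infer_query_length() == 101
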