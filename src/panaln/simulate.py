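"""Synthetic genomes, variant sets and Illumina-like reads with ground truth.

The generator emulates the standard short-read benchmarking setup: a random
reference, planted SNVs and short INDELs written as a VCF, and 101-bp reads
drawn uniformly from both strands that carry each overlapped variant allele
with probability 0.5 (diploid-like) and acquire i.i.d. substitution
sequencing errors at a 0.2% per-base rate.  Three regimes are expressible
through the config: variants+errors (the realistic default), variants only,
and errors only.  Every read's origin span, strand, carried variants and
error offsets are recorded so alignments can be scored against the truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pysam

log = logging.getLogger(__name__)

from .pangenome import ReferenceGenome, VariantSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    genome_length: int = 100_000
    n_chromosomes: int = 1
    snv_count: int = 1000
    indel_count: int = 100
    indel_len_max: int = 10
    read_length: int = 101
    read_count: int = 10_000
    error_rate: float = 0.002
    variant_prob: float = 0.5    # chance a read carries an overlapped allele
    seed: int = 42

    def __post_init__(self):
        if not 0.0 <= self.error_rate <= 1.0 or not 0.0 <= self.variant_prob <= 1.0:
            raise ValueError("rates must be in [0, 1]")
        if min(self.genome_length, self.n_chromosomes, self.read_length,
               self.read_count + 1, self.indel_len_max) <= 0:
            raise ValueError("counts must be positive")


@dataclass
class TruthRecord:
    read_id: str
    chrom: str
    start: int              # 1-based inclusive origin span on the chromosome
    end: int
    strand: str
    error_offsets: tuple    # positions within the read (read orientation)
    variants: tuple         # (kind, chrom_pos) pairs the read carries


def simulate_genome(cfg: SimConfig):
    """Random reference plus non-overlapping planted variants.

    SNV positions are distinct; INDELs do not overlap SNVs or each other and
    stay clear of chromosome edges.  Raises when the requested counts cannot
    be placed.
    """
    rng = np.random.default_rng(cfg.seed)
    per = cfg.genome_length // cfg.n_chromosomes
    chroms = []
    for i in range(cfg.n_chromosomes):
        seq = _BASES[rng.integers(0, 4, per)].tobytes().decode()
        chroms.append((f"chr{i + 1}", seq))
    ref = ReferenceGenome(chroms)

    pad = cfg.indel_len_max + 2
    capacity = cfg.n_chromosomes * max(0, per - 2 * cfg.read_length)
    if cfg.snv_count + cfg.indel_count * (pad + 1) > capacity:
        raise ValueError("variant counts exceed genome capacity")

    vs = VariantSet()
    taken = set()  # (chrom_idx, pos) sites blocked for further placement
    # INDELs first: they need clear spans
    placed = 0
    while placed < cfg.indel_count:
        ci = int(rng.integers(0, cfg.n_chromosomes))
        name, seq = chroms[ci]
        pos = int(rng.integers(cfg.read_length, per - cfg.read_length - pad))
        ilen = int(rng.integers(1, cfg.indel_len_max + 1))
        span = range(pos - 1, pos + ilen + 1)
        if any((ci, p) in taken for p in span):
            continue
        if rng.random() < 0.5:  # insertion after pos
            ins = _BASES[rng.integers(0, 4, ilen)].tobytes().decode()
            vs.indels.append((name, pos, seq[pos - 1], seq[pos - 1] + ins))
        else:                   # deletion of ilen bases after pos
            vs.indels.append(
                (name, pos, seq[pos - 1:pos + ilen], seq[pos - 1])
            )
        taken.update((ci, p) for p in span)
        placed += 1
    placed = 0
    while placed < cfg.snv_count:
        ci = int(rng.integers(0, cfg.n_chromosomes))
        name, seq = chroms[ci]
        pos = int(rng.integers(1, per + 1))
        if (ci, pos) in taken:
            continue
        refb = seq[pos - 1]
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == refb:
            alt = "ACGT"[int(rng.integers(0, 4))]
        vs.snvs.append((name, pos, refb, (alt,)))
        taken.add((ci, pos))
        placed += 1
    vs.snvs.sort(key=lambda r: (r[0], r[1]))
    vs.indels.sort(key=lambda r: (r[0], r[1]))
    return ref, vs


def simulate_reads(ref: ReferenceGenome, vs: VariantSet, cfg: SimConfig):
    """Draw reads from both strands, apply carried variants and errors.

    Returns ``(reads, truth)`` with reads as (id, sequence) pairs.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    L = cfg.read_length
    by_chrom_snv = {}
    for chrom, pos, refb, alts in vs.snvs:
        alts = (alts,) if isinstance(alts, str) else alts
        by_chrom_snv.setdefault(chrom, {})[pos] = alts
    by_chrom_indel = {}
    for chrom, pos, rall, aall in vs.indels:
        by_chrom_indel.setdefault(chrom, {})[pos] = (rall, aall)

    comp = str.maketrans("ACGTN", "TGCAN")
    reads, truth = [], []
    for ridx in range(cfg.read_count):
        ci = int(rng.integers(0, len(ref.chroms)))
        name, seq = ref.chroms[ci]
        if len(seq) < L + cfg.indel_len_max * 2 + 2:
            raise ValueError("read length exceeds chromosome")
        start = int(rng.integers(1, len(seq) - L - cfg.indel_len_max * 2))
        snvs = by_chrom_snv.get(name, {})
        indels = by_chrom_indel.get(name, {})
        out = []
        carried = []
        p = start  # 1-based walker
        while len(out) < L:
            b = seq[p - 1]
            if p in snvs and rng.random() < cfg.variant_prob:
                alts = snvs[p]
                b = alts[int(rng.integers(0, len(alts)))]
                carried.append(("snv", p))
            out.append(b)
            if p in indels and rng.random() < cfg.variant_prob:
                rall, aall = indels[p]
                if len(rall) == 1:  # insertion after p
                    out.extend(aall[1:])
                    carried.append(("ins", p))
                else:               # deletion of the bases after p
                    p += len(rall) - 1
                    carried.append(("del", p))
            p += 1
        end = p - 1
        segment = "".join(out[:L])

        strand = "+" if rng.random() < 0.5 else "-"
        read = segment if strand == "+" else segment.translate(comp)[::-1]
        errs = np.flatnonzero(rng.random(L) < cfg.error_rate)
        if len(errs):
            arr = list(read)
            for i in errs:
                cur = arr[i]
                alt = "ACGT"[int(rng.integers(0, 4))]
                while alt == cur:
                    alt = "ACGT"[int(rng.integers(0, 4))]
                arr[i] = alt
            read = "".join(arr)
        rid = f"r{ridx:06d}"
        reads.append((rid, read))
        truth.append(TruthRecord(rid, name, start, end, strand,
                                 tuple(int(i) for i in errs), tuple(carried)))
    return reads, truth


def write_truth(truth, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\tstrand\terrors\tvariants\n")
        for t in truth:
            errs = ",".join(map(str, t.error_offsets)) or "."
            var = ",".join(f"{k}:{p}" for k, p in t.variants) or "."
            fh.write(f"{t.read_id}\t{t.chrom}\t{t.start}\t{t.end}\t"
                     f"{t.strand}\t{errs}\t{var}\n")


def read_truth(path: str):
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, chrom, s, e, strand, errs, var = line.rstrip("\n").split("\t")
            eo = tuple(int(x) for x in errs.split(",")) if errs != "." else ()
            vv = tuple(tuple(x.split(":")) for x in var.split(",")) if var != "." else ()
            out.append(TruthRecord(rid, chrom, int(s), int(e), strand, eo, vv))
    return out


def score_alignments(sam_path: str, truth) -> dict:
    """Mapped and correctly-mapped ratios under the 90%-overlap criterion.

    A read counts as correctly mapped when its primary alignment is on the
    truth chromosome and the reported reference span overlaps the recorded
    origin span by at least 90% of the read length.
    """
    by_id = {t.read_id: t for t in truth}
    n = len(by_id)
    mapped = correct = seen = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_secondary or rec.is_supplementary:
                continue
            t = by_id.get(rec.query_name)
            if t is None:
                raise ValueError(f"read id {rec.query_name} not in truth set")
            seen += 1
            if rec.is_unmapped:
                continue
            mapped += 1
            read_len = len(rec.query_sequence) if rec.query_sequence else 0
            # half-open 1-based spans on the reference
            span_lo = rec.reference_start + 1
            span_hi = (rec.reference_end or rec.reference_start) + 1
            ov = min(span_hi, t.end + 1) - max(span_lo, t.start)
            if rec.reference_name == t.chrom and ov >= 0.9 * read_len:
                correct += 1
    if seen != n:
        raise ValueError(f"SAM covers {seen} of {n} truth reads")
    return {
        "n_reads": n,
        "mapped": mapped,
        "correct": correct,
        "mapped_ratio": mapped / n if n else 0.0,
        "correct_ratio": correct / n if n else 0.0,
    }
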