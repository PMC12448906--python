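"""Reading and writing the standard text formats (FASTA, VCF, FASTQ, TSV)."""

from __future__ import annotations

import logging

import pysam

from .pangenome import ReferenceGenome, VariantSet

log = logging.getLogger(__name__)


def read_fasta(path: str) -> ReferenceGenome:
    """Multi-sequence FASTA (wrapped or unwrapped, gzip accepted)."""
    chroms = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            chroms.append((entry.name, entry.sequence.upper()))
    if not chroms:
        raise ValueError(f"no sequences found in {path}")
    return ReferenceGenome(chroms)


def read_vcf(path: str) -> VariantSet:
    """VCF v4.x, CHROM/POS/REF/ALT columns only; multi-allelic ALT lists are
    split; records that are neither SNVs nor simple INDELs are dropped."""
    vs = VariantSet()
    opener = _opener(path)
    lineno = 0
    with opener(path) as fh:
        for raw in fh:
            lineno += 1
            line = raw.decode() if isinstance(raw, bytes) else raw
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: malformed VCF record")
            chrom, pos_s, _id, ref, alts = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad POS {pos_s!r}") from exc
            ref = ref.upper()
            for alt in alts.upper().split(","):
                if alt in (".", "<*>", "*") or not alt.isalpha():
                    continue
                if len(ref) == 1 and len(alt) == 1:
                    vs.snvs.append((chrom, pos, ref, (alt,)))
                elif len(ref) == 1 or len(alt) == 1:
                    vs.indels.append((chrom, pos, ref, alt))
                else:
                    log.warning("%s:%d: complex variant skipped", path, lineno)
    return vs


def _opener(path):
    import gzip
    with open(path, "rb") as fh:
        magic = fh.read(2)
    return gzip.open if magic == b"\x1f\x8b" else open


def read_fastq(path: str):
    """Yield (name, sequence, quality) from FASTQ (gzip accepted)."""
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            yield entry.name, entry.sequence.upper(), entry.quality or "*"


def write_fasta(ref: ReferenceGenome, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in ref.chroms:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_vcf(ref: ReferenceGenome, vs: VariantSet, path: str) -> None:
    recs = []
    for chrom, pos, rbase, alts in vs.snvs:
        if isinstance(alts, str):
            alts = (alts,)
        recs.append((chrom, pos, rbase, ",".join(alts)))
    for chrom, pos, rall, aall in vs.indels:
        recs.append((chrom, pos, rall, aall))
    order = {name: i for i, name in enumerate(ref.names)}
    recs.sort(key=lambda r: (order.get(r[0], 99), r[1]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=panaln-simulate\n")
        for name, seq in ref.chroms:
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref_a, alt_a in recs:
            fh.write(f"{chrom}\t{pos}\t.\t{ref_a}\t{alt_a}\t.\tPASS\t.\n")


def write_fastq(reads, path: str) -> None:
    """reads: iterable of (name, sequence)."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")
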