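"""Linear pangenome representation.

A reference genome plus a VCF of small variants is flattened into a single
symbol string T:

* every SNV site on the backbone is rewritten as the IUPAC code of the union
  of its alleles (``A/T`` becomes ``W``), so SNPs cost no extra space and no
  graph structure;
* every short insertion or deletion becomes a *padded fragment* -- the
  alternate allele (or the joined flanks, for a deletion) surrounded by up to
  ``context_k`` bases of reference context -- appended after the backbone,
  each fragment preceded by the separator ``#``.

The annotation table ``Ann`` maps positions in T back to chromosome
coordinates; the aligner indexes ``T + reverse_complement(T) + '$'``.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .iupac import CODE_OF_BASESET, COMPLEMENT, encode

log = logging.getLogger(__name__)

DEFAULT_CONTEXT_K = 101
MAX_INDEL_LEN = 50

BACKBONE, INSERTION, DELETION = 0, 1, 2
_KIND_NAMES = {BACKBONE: "backbone", INSERTION: "insertion", DELETION: "deletion"}


@dataclass
class ReferenceGenome:
    """Ordered (name, sequence) chromosomes over A/C/G/T/N."""

    chroms: list  # list[tuple[str, str]]

    def __post_init__(self):
        names = [n for n, _ in self.chroms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        if any(len(s) == 0 for _, s in self.chroms):
            raise ValueError("empty chromosome sequence")

    @property
    def names(self):
        return [n for n, _ in self.chroms]

    def seq(self, name: str) -> str:
        for n, s in self.chroms:
            if n == name:
                return s
        raise KeyError(name)


@dataclass
class VariantSet:
    """SNVs ``(chrom, pos, ref, alts)`` and simple INDELs ``(chrom, pos, ref, alt)``.

    Positions are 1-based (VCF convention).  An INDEL has exactly one of
    ``|ref| == 1`` (insertion) or ``|alt| == 1`` (deletion).
    """

    snvs: list = field(default_factory=list)
    indels: list = field(default_factory=list)


@dataclass
class AnnRecord:
    text_start: int      # 0-based half-open span of the record's content in T
    text_end: int
    chrom_id: int
    kind: int            # BACKBONE / INSERTION / DELETION
    vcf_pos: int         # 1-based anchor: last left-context base (fragments) or 0
    left_len: int        # fragment left-context length
    mid_len: int         # inserted-allele length (insertions only)
    del_len: int         # deleted span length (deletions only)

    @property
    def anchor_pos(self) -> int:
        """1-based chromosome coordinate of the record's first base."""
        if self.kind == BACKBONE:
            return 1
        return self.vcf_pos - self.left_len + 1

    @property
    def variant_kind(self) -> str:
        return _KIND_NAMES[self.kind]


class AnnotationTable:
    """Maps positions of T to chromosome coordinates.

    Backbone spans map by offset; positions inside a padded fragment map
    through the fragment's anchor, adjusting for the inserted or deleted
    bases.  Separator positions (``#``) carry no biological coordinate.
    """

    def __init__(self, records, chrom_names, chrom_lengths):
        self.records = sorted(records, key=lambda r: r.text_start)
        self.chrom_names = list(chrom_names)
        self.chrom_lengths = list(chrom_lengths)
        self._starts = [r.text_start for r in self.records]

    def find(self, text_pos: int) -> AnnRecord | None:
        i = bisect.bisect_right(self._starts, text_pos) - 1
        if i >= 0:
            r = self.records[i]
            if r.text_start <= text_pos < r.text_end:
                return r
        return None

    def project(self, text_pos: int, match_len: int = 1):
        """Chromosome name, 1-based position and inside-indel flag for a
        match starting at ``text_pos`` and spanning ``match_len`` symbols.

        Raises ``ValueError`` on separator positions and on spans that cross
        a record boundary (no single biological locus).
        """
        r = self.find(text_pos)
        if r is None:
            raise ValueError(f"position {text_pos} is on a separator/outside T")
        if text_pos + match_len > r.text_end:
            raise ValueError("span crosses a fragment/chromosome boundary")
        o = text_pos - r.text_start
        chrom = self.chrom_names[r.chrom_id]
        if r.kind == BACKBONE:
            return chrom, o + 1, False
        p, L = r.vcf_pos, r.left_len
        if o < L:
            pos = r.anchor_pos + o
        elif r.kind == INSERTION and o < L + r.mid_len:
            pos = p  # inside the inserted allele: last reference base before it
        else:
            pos = p + r.del_len + 1 + (o - L - r.mid_len)
        return chrom, pos, True

    # serialization helpers -------------------------------------------------

    def to_arrays(self):
        recs = np.array(
            [
                (r.text_start, r.text_end, r.chrom_id, r.kind, r.vcf_pos,
                 r.left_len, r.mid_len, r.del_len)
                for r in self.records
            ],
            dtype=np.int64,
        ).reshape(len(self.records), 8)
        return recs

    @classmethod
    def from_arrays(cls, recs, chrom_names, chrom_lengths):
        records = [AnnRecord(*map(int, row)) for row in recs]
        return cls(records, chrom_names, chrom_lengths)


@dataclass
class PangenomeText:
    """The assembled linear representation and its double-stranded text."""

    T: str
    full_text: np.ndarray       # uint8 codes of T + revcomp(T) + '$'
    context_k: int
    ann: AnnotationTable

    @property
    def t_len(self) -> int:
        return len(self.T)


def randomize_ambiguous(ref: ReferenceGenome, seed: int) -> ReferenceGenome:
    """Replace every 'N' with a uniformly random base, deterministically."""
    rng = np.random.default_rng(seed)
    out = []
    for name, seq in ref.chroms:
        if "N" in seq:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
            mask = arr == ord("N")
            arr[mask] = np.frombuffer(b"ACGT", dtype=np.uint8)[
                rng.integers(0, 4, int(mask.sum()))
            ]
            seq = arr.tobytes().decode()
        out.append((name, seq))
    return ReferenceGenome(out)


def encode_snps(ref: ReferenceGenome, variants: VariantSet) -> str:
    """IUPAC-encode all SNV sites onto the concatenated backbone.

    Multi-allelic sites merge into one code over the allele union; a site
    whose union would be all four bases keeps the reference plus the first
    two alternates (the alphabet excludes the four-base code).  Records whose
    stated reference base disagrees with the genome are dropped with a
    warning.
    """
    by_site: dict = {}
    for chrom, pos, rbase, alts in variants.snvs:
        if isinstance(alts, str):
            alts = (alts,)
        site = by_site.setdefault((chrom, pos), {"ref": rbase, "alts": []})
        for a in alts:
            if a not in site["alts"]:
                site["alts"].append(a)

    pieces = []
    for name, seq in ref.chroms:
        arr = bytearray(seq.encode())
        for (chrom, pos), site in by_site.items():
            if chrom != name:
                continue
            if not 1 <= pos <= len(seq):
                log.warning("SNV %s:%d outside chromosome; dropped", chrom, pos)
                continue
            if site["ref"] != seq[pos - 1]:
                log.warning(
                    "SNV %s:%d ref %s does not match genome %s; dropped",
                    chrom, pos, site["ref"], seq[pos - 1],
                )
                continue
            alleles = {site["ref"]} | {a for a in site["alts"] if a in "ACGT"}
            if len(alleles) == 4:
                kept = [site["ref"]] + site["alts"][:2]
                log.warning(
                    "SNV %s:%d covers all four bases; truncated to %s",
                    chrom, pos, "".join(kept),
                )
                alleles = set(kept)
            arr[pos - 1] = ord(CODE_OF_BASESET[frozenset(alleles)])
        pieces.append(arr.decode())
    return "".join(pieces)


def build_indel_fragments(ref: ReferenceGenome, variants: VariantSet,
                          context_k: int = DEFAULT_CONTEXT_K):
    """Padded fragment strings plus their annotation records.

    Insertion at pos p (ref ``X``, alt ``X``+ins): left context ends at p,
    then the inserted bases, then context from p+1.  Deletion at pos p (ref
    ``X``+del, alt ``X``): left context ends at p, right context resumes
    after the deleted span.  Context is truncated, never an error, at
    chromosome edges.  Text coordinates in the returned records are relative
    to the fragment block and are finalized by :func:`assemble_text`.
    """
    if context_k < 1:
        raise ValueError("context_k must be >= 1")
    chrom_ids = {name: i for i, name in enumerate(ref.names)}
    fragments, records = [], []
    seen = set()
    for chrom, pos, rallele, aallele in variants.indels:
        if (chrom, pos) in seen:
            log.warning("duplicate INDEL at %s:%d; first record wins", chrom, pos)
            continue
        if chrom not in chrom_ids:
            log.warning("INDEL on unknown chromosome %s; dropped", chrom)
            continue
        seq = ref.seq(chrom)
        if not (len(rallele) == 1) ^ (len(aallele) == 1):
            if len(rallele) == 1 and len(aallele) == 1:
                log.warning("INDEL at %s:%d is a SNV; dropped", chrom, pos)
                continue
            log.warning("complex INDEL at %s:%d unsupported; dropped", chrom, pos)
            continue
        if max(len(rallele), len(aallele)) - 1 > MAX_INDEL_LEN:
            log.warning("INDEL at %s:%d longer than %d bp; skipped",
                        chrom, pos, MAX_INDEL_LEN)
            continue
        if not 1 <= pos <= len(seq) or seq[pos - 1] != rallele[0]:
            log.warning("INDEL %s:%d ref mismatch; dropped", chrom, pos)
            continue
        seen.add((chrom, pos))
        if len(rallele) == 1:  # insertion
            ins = aallele[1:]
            L = min(context_k, pos)
            R = min(context_k, len(seq) - pos)
            frag = seq[pos - L:pos] + ins + seq[pos:pos + R]
            rec = AnnRecord(0, len(frag), chrom_ids[chrom], INSERTION,
                            pos, L, len(ins), 0)
        else:  # deletion
            dl = len(rallele) - 1
            if pos + dl > len(seq) or seq[pos - 1:pos - 1 + len(rallele)] != rallele:
                log.warning("deletion %s:%d ref mismatch; dropped", chrom, pos)
                continue
            L = min(context_k, pos)
            R = min(context_k, len(seq) - pos - dl)
            frag = seq[pos - L:pos] + seq[pos + dl:pos + dl + R]
            rec = AnnRecord(0, len(frag), chrom_ids[chrom], DELETION,
                            pos, L, 0, dl)
        if "#" in frag or "N" in frag:
            log.warning("fragment at %s:%d contains invalid symbols; dropped",
                        chrom, pos)
            continue
        fragments.append(frag)
        records.append(rec)
    return fragments, records


def assemble_text(backbone: str, fragments) -> str:
    """``backbone # frag1 # frag2 ...`` -- a '#' before each fragment."""
    for f in fragments:
        if "#" in f:
            raise ValueError("fragment contains the separator '#'")
    return backbone + "".join("#" + f for f in fragments)


def reverse_complement(s: str) -> str:
    """Reverse-complement a symbol string (IUPAC-aware; '#' is its own
    complement; '$' is not allowed)."""
    if "$" in s:
        raise ValueError("'$' has no complement")
    return "".join(COMPLEMENT[c] for c in reversed(s))


def build_pangenome(ref: ReferenceGenome, variants: VariantSet,
                    context_k: int = DEFAULT_CONTEXT_K,
                    seed: int = 0) -> PangenomeText:
    """Run the full representation pipeline: N-randomization, SNP encoding,
    fragment padding, assembly and annotation."""
    ref = randomize_ambiguous(ref, seed)
    backbone = encode_snps(ref, variants)
    fragments, frag_recs = build_indel_fragments(ref, variants, context_k)
    T = assemble_text(backbone, fragments)

    records = []
    off = 0
    for cid, (name, seq) in enumerate(ref.chroms):
        records.append(AnnRecord(off, off + len(seq), cid, BACKBONE, 0, 0, 0, 0))
        off += len(seq)
    pos = len(backbone)
    for frag, rec in zip(fragments, frag_recs):
        pos += 1  # the separator
        rec.text_start, rec.text_end = pos, pos + len(frag)
        records.append(rec)
        pos += len(frag)
    assert pos == len(T)

    ann = AnnotationTable(records, ref.names, [len(s) for _, s in ref.chroms])
    full = np.concatenate([
        encode(T), encode(reverse_complement(T)),
        np.array([iupac.SENTINEL], dtype=np.uint8),
    ])
    return PangenomeText(T=T, full_text=full, context_k=context_k, ann=ann)


def project_position(ann: AnnotationTable, text_pos: int, match_len: int = 1):
    """Functional wrapper over :meth:`AnnotationTable.project`."""
    return ann.project(text_pos, match_len)
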