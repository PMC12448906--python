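"""Seed-and-extend read alignment against the pangenome index.

Pipeline per read: compute the paired D arrays and cut the read into equal
overlapping fragments; use the longest (LEOF) as the seed, falling back to
the next-longest whenever a seed has no occurrences; locate the seed's hits;
extract a margin-padded candidate window around every hit straight from the
index; align the read to each window with the IUPAC-aware wavefront
aligner (read end-to-end, window flanks free); report the cheapest
candidate, with a mapping quality derived from the cost gap to the runner-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import __version__ as _pkg_version
from .fmindex import PanalnIndex
from .iupac import BASE_INDEX, COMPAT
from .queries import count, locate
from .seeding import find_leof, revcomp_read
from .wfa import Penalties, wfa_align

DEFAULT_MIN_SEED = 19
DEFAULT_MAX_HITS = 64
#: alignment cost ceiling; candidates beyond it are hopeless and dropped
DEFAULT_MAX_SCORE = 80
#: MAPQ ceiling for reads whose best seed is shorter than min_seed
SHORT_SEED_MAPQ = 20


@dataclass
class AlignParams:
    penalties: Penalties = field(default_factory=Penalties)
    min_seed: int = DEFAULT_MIN_SEED
    max_hits: int = DEFAULT_MAX_HITS
    max_score: int = DEFAULT_MAX_SCORE

    def margin(self, read_len: int) -> int:
        """Window padding to absorb INDELs: max(16, 10% of the read)."""
        return max(16, -(-read_len // 10))


@dataclass
class CandidateWindow:
    text_start: int
    codes: np.ndarray
    hit_text_pos: int
    strand: str

    @property
    def length(self) -> int:
        return len(self.codes)


@dataclass
class AlignmentRecord:
    read_id: str
    flag: int
    chrom: str
    pos: int               # 1-based; 0 when unmapped
    mapq: int
    cigar: str
    seq: str
    score: int | None      # WFA cost of the primary alignment
    qual: str = "*"

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & 4)


def make_windows(index: PanalnIndex, hits, read_len: int, seed_start: int,
                 seed_len: int, params: AlignParams) -> list:
    """Margin-padded extension candidates around seed hits.

    The window is predicted from where the seed sits in the read and clipped
    at separator/chromosome boundaries (the Ann record containing the hit);
    a hit whose window vanishes entirely is dropped.
    """
    margin = params.margin(read_len)
    out = []
    for h in hits:
        rec = index.ann.find(h.text_pos)
        if rec is None:
            continue
        if h.strand == "+":
            off = seed_start
        else:  # the seed occupies the mirrored span of the oriented read
            off = read_len - (seed_start + seed_len)
        pred = h.text_pos - off
        lo = max(rec.text_start, pred - margin)
        hi = min(rec.text_end, pred + read_len + margin)
        if hi <= lo:
            continue
        codes = index.extract_codes(lo, hi - lo)
        out.append(CandidateWindow(lo, codes, h.text_pos, h.strand))
    return out


def _fast_exact(read_oriented, window: CandidateWindow, pred: int):
    """Zero-cost check at the predicted position (skips WFA for clean reads)."""
    off = pred - window.text_start
    if off < 0 or off + len(read_oriented) > window.length:
        return None
    seg = window.codes[off: off + len(read_oriented)]
    idxs = [BASE_INDEX.get(b, -1) for b in read_oriented]
    if -1 in idxs:
        return None
    if COMPAT[idxs, seg].all():
        return 0, f"{len(read_oriented)}M", pred, pred + len(read_oriented)
    return None


def align_read(index: PanalnIndex, read_id: str, read: str,
               params: AlignParams | None = None) -> list:
    """Align one read; returns a single-record list (primary or unmapped)."""
    params = params or AlignParams()
    read = read.upper()
    part = find_leof(index, read)
    fragments = sorted(part.fragments, key=lambda f: (-(f[1] - f[0]), f[0]))
    rc = revcomp_read(read)

    candidates = {}
    repetitive = False
    used_seed_len = 0
    for s, e in fragments:
        if e - s == 0:
            continue
        seed = read[s:e]
        iv = count(index, seed)
        if iv.width == 0:
            continue
        if iv.truncated:
            repetitive = True
        hits = locate(index, iv, e - s, max_hits=params.max_hits)
        if not hits:
            continue
        if len(hits) >= params.max_hits:
            repetitive = True
        used_seed_len = e - s
        windows = make_windows(index, hits, len(read), s, e - s, params)
        for w in windows:
            oriented = read if w.strand == "+" else rc
            off = s if w.strand == "+" else len(read) - e
            pred = w.hit_text_pos - off
            res = _fast_exact(oriented, w, pred)
            if res is None:
                aln = wfa_align(oriented, w.codes, params.penalties,
                                text_ends_free=True,
                                max_score=params.max_score)
                if aln is None:
                    continue
                res = (aln.score, aln.cigar,
                       w.text_start + aln.text_start,
                       w.text_start + aln.text_end)
            score, cigar, tstart, tend = res
            try:
                chrom, pos, inside = index.ann.project(tstart, tend - tstart)
            except ValueError:
                continue
            key = (chrom, pos, w.strand)
            if key not in candidates or score < candidates[key][0]:
                candidates[key] = (score, cigar, chrom, pos, w.strand)
        if candidates:
            break  # seed produced extendable hits; no further fallback

    if not candidates:
        return [AlignmentRecord(read_id, 4, "*", 0, 0, "*", read, None)]

    ranked = sorted(candidates.values(),
                    key=lambda c: (c[0], c[2], c[3], c[4]))
    score, cigar, chrom, pos, strand = ranked[0]
    if repetitive:
        mapq = 0
    elif len(ranked) == 1:
        mapq = 60
    else:
        mapq = min(60, 6 * (ranked[1][0] - score))
    if used_seed_len < params.min_seed:
        mapq = min(mapq, SHORT_SEED_MAPQ)
    flag = 16 if strand == "-" else 0
    seq = rc if strand == "-" else read
    return [AlignmentRecord(read_id, flag, chrom, pos, mapq, cigar, seq, score)]


def write_sam(records, index: PanalnIndex, path, command_line: str = "panaln"):
    """Emit SAM v1.6 with @HD/@SQ headers from the index chromosome table."""
    close = False
    if isinstance(path, (str, bytes)):
        fh = open(path, "w")
        close = True
    else:
        fh = path
    try:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, length in zip(index.ann.chrom_names, index.ann.chrom_lengths):
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        fh.write(f"@PG\tID:panaln\tPN:panaln\tVN:{_pkg_version}"
                 f"\tCL:{command_line}\n")
        for r in records:
            if r.is_unmapped:
                fh.write(f"{r.read_id}\t4\t*\t0\t0\t*\t*\t0\t0\t{r.seq}\t{r.qual}\n")
            else:
                tags = f"AS:i:{-r.score}"
                fh.write(
                    f"{r.read_id}\t{r.flag}\t{r.chrom}\t{r.pos}\t{r.mapq}\t"
                    f"{r.cigar}\t*\t0\t0\t{r.seq}\t{r.qual}\t{tags}\n"
                )
    finally:
        if close:
            fh.close()
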