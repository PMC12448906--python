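"""Fundamental pangenome queries: count, locate, extract.

Because SNP alleles are folded into IUPAC symbols, a plain DNA pattern can be
*compatible* with several distinct strings in the text (``TAA`` matches
``TAA`` and ``TWA``), so its occurrences occupy a *set* of suffix-array
intervals rather than one.  Backward search therefore carries an interval
set: each step maps every interval through ``C[c] + Occ_c`` for every symbol
``c`` in the compatibility class of the next read base, batching the Occ
queries across symbols and interval boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fmindex import PanalnIndex
from .iupac import GAMMA_CODES, decode

#: Bound on the number of SA intervals tracked during backward search.  When
#: exceeded, the widest intervals are kept and the set is flagged truncated;
#: a truncated count is a lower bound and the seed is treated as repetitive.
MAX_INTERVALS = 64


@dataclass
class IntervalSet:
    """A set of inclusive SA intervals ``[lo, hi]``."""

    lo: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    hi: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    truncated: bool = False

    @classmethod
    def full(cls, n: int) -> "IntervalSet":
        return cls(np.array([0], dtype=np.int64), np.array([n - 1], dtype=np.int64))

    @property
    def width(self) -> int:
        """Total number of occurrences covered."""
        if len(self.lo) == 0:
            return 0
        return int((self.hi - self.lo + 1).sum())

    def __len__(self) -> int:
        return len(self.lo)

    def is_empty(self) -> bool:
        return len(self.lo) == 0

    def normalized(self) -> "IntervalSet":
        """Sort and merge touching/overlapping intervals; cap the set size."""
        if len(self.lo) == 0:
            return self
        order = np.argsort(self.lo, kind="stable")
        lo, hi = self.lo[order], self.hi[order]
        merged_lo, merged_hi = [lo[0]], [hi[0]]
        for a, b in zip(lo[1:], hi[1:]):
            if a <= merged_hi[-1] + 1:
                merged_hi[-1] = max(merged_hi[-1], b)
            else:
                merged_lo.append(a)
                merged_hi.append(b)
        lo = np.array(merged_lo, dtype=np.int64)
        hi = np.array(merged_hi, dtype=np.int64)
        truncated = self.truncated
        if len(lo) > MAX_INTERVALS:
            widths = hi - lo
            keep = np.sort(np.argsort(widths)[::-1][:MAX_INTERVALS])
            lo, hi = lo[keep], hi[keep]
            truncated = True
        return IntervalSet(lo, hi, truncated)


@dataclass(frozen=True)
class Hit:
    """One located occurrence, projected to chromosome coordinates."""

    chrom: str
    pos: int            # 1-based
    strand: str         # "+" or "-"
    inside_indel: bool
    text_pos: int       # 0-based forward-strand position in T


def backward_step(index: PanalnIndex, s: IntervalSet, base: str) -> IntervalSet:
    """Prepend one read base: map every interval through every compatible
    IUPAC symbol.  'N' (and any non-ACGT base) matches nothing."""
    if s.is_empty():
        return s
    codes = GAMMA_CODES.get(base)
    if codes is None:
        return IntervalSet(truncated=s.truncated)
    m = len(s.lo)
    pos = np.concatenate([s.lo, s.hi + 1])  # exclusive boundary queries
    occ = index.occ_batch_excl(pos, tuple(int(c) for c in codes))
    los, his = [], []
    for c in codes:
        c = int(c)
        cnt = occ[c]
        lo = index.C[c] + cnt[:m]
        hi = index.C[c] + cnt[m:] - 1
        keep = lo <= hi
        if keep.any():
            los.append(lo[keep])
            his.append(hi[keep])
    if not los:
        return IntervalSet(truncated=s.truncated)
    out = IntervalSet(np.concatenate(los), np.concatenate(his), s.truncated)
    return out.normalized()


def count(index: PanalnIndex, pattern: str) -> IntervalSet:
    """Backward search of a DNA pattern; the result's width is the number of
    compatible occurrences (a lower bound if the set was truncated).

    Runs the compiled stepping loop; :func:`count_py` is the uncompiled
    equivalent built from :func:`backward_step`.
    """
    if len(pattern) == 0:
        return IntervalSet.full(index.n)
    from ._kernels import count_kernel
    f = index.flat
    pat = _base_codes(pattern)
    lo, hi, m, trunc = count_kernel(
        pat, np.int64(index.n), index._gamma, index._glen,
        np.int64(MAX_INTERVALS), *f,
    )
    return IntervalSet(lo, hi, bool(trunc))


def _base_codes(pattern: str) -> np.ndarray:
    """Read bases as 0..3 (A/C/G/T), -1 for anything else."""
    lut = np.full(256, -1, dtype=np.int8)
    for b, i in (("A", 0), ("C", 1), ("G", 2), ("T", 3)):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    return lut[np.frombuffer(pattern.encode(), dtype=np.uint8)].astype(np.int64)


def count_py(index: PanalnIndex, pattern: str) -> IntervalSet:
    """Pure backward_step composition (reference path)."""
    if len(pattern) == 0:
        return IntervalSet.full(index.n)
    s = IntervalSet.full(index.n)
    for base in reversed(pattern):
        s = backward_step(index, s, base)
        if s.is_empty():
            break
    return s


def locate(index: PanalnIndex, s: IntervalSet, pattern_len: int,
           max_hits: int = MAX_INTERVALS) -> list:
    """Resolve an interval set to deduplicated, sorted chromosome hits.

    Rows landing in the reverse-complement half are reflected to forward
    coordinates with strand '-'; spans crossing a separator or chromosome
    boundary are discarded (they have no biological locus).
    """
    hits = set()
    resolved = 0
    for lo, hi in zip(s.lo, s.hi):
        for row in range(int(lo), int(hi) + 1):
            if resolved >= max_hits:
                break
            resolved += 1
            tp = index.sa_lookup(int(row))
            if getattr(index, "single_strand", False):
                fwd, strand = tp, "+"
            elif tp >= index.t_len:
                fwd = 2 * index.t_len - tp - pattern_len
                strand = "-"
            else:
                fwd, strand = tp, "+"
            if fwd < 0 or fwd + pattern_len > index.t_len:
                continue
            try:
                chrom, cpos, inside = index.ann.project(fwd, pattern_len)
            except ValueError:
                continue
            hits.add(Hit(chrom, cpos, strand, inside, fwd))
    return sorted(hits, key=lambda h: (h.chrom, h.pos, h.strand))


def extract(index: PanalnIndex, text_pos: int, length: int) -> str:
    """Length-``length`` substring of the indexed text starting at
    ``text_pos``, reconstructed from the index itself."""
    return decode(index.extract_codes(text_pos, length))
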