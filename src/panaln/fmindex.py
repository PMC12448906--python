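"""The split wavelet-tree FM-index.

The BWT W of the double-stranded pangenome text is partitioned by alphabet:
a bitvector U marks positions carrying polymorphic symbols (IUPAC codes,
'#', '$'), the unique-base subsequence Wl goes into a balanced wavelet tree
and the polymorphic subsequence Wr into a Huffman-shaped one.  An Occ query
first routes through U, then descends one (or, for a batched symbol set,
both) of the trees.  A sampled suffix array resolves rows to text positions
by LF-walking to the nearest sampled row; inverse-SA samples support
substring extraction straight from the index.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from . import iupac
from .bitvector import RankBitvector
from .iupac import IS_POLY, NSYM, SENTINEL, SYMBOL_ORDER
from .pangenome import AnnotationTable, PangenomeText
from .wavelet import WaveletTree

log = logging.getLogger(__name__)

MAGIC = b"PANALN-LITE\x00"
VERSION = 1
DEFAULT_SA_STEP = 8

UNIQ_CODES = tuple(int(i) for i in np.flatnonzero(~IS_POLY))
POLY_CODES = tuple(int(i) for i in np.flatnonzero(IS_POLY))


class IndexFormatError(Exception):
    """Raised when an index file is corrupt or has the wrong version."""


def build_suffix_array(text: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort).

    ``text`` is a uint8 code array that must end with the unique sentinel.
    """
    text = np.asarray(text, dtype=np.uint8)
    n = len(text)
    if n == 0 or text[-1] != SENTINEL or (text == SENTINEL).sum() != 1:
        raise ValueError("text must end with exactly one '$'")
    rank = text.astype(np.int64)
    sa = np.argsort(rank, kind="stable")
    rank = _rerank(rank[sa][None, :])
    k = 1
    inv = np.empty(n, dtype=np.int64)
    while rank.max() < n - 1:
        inv[sa] = rank  # rank per position
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: max(0, n - k)] = inv[k:]
        sa = np.lexsort((key2, inv))
        rank = _rerank(np.stack([inv[sa], key2[sa]]))
        k *= 2
    return sa


def _rerank(sorted_keys: np.ndarray) -> np.ndarray:
    """Dense ranks (0-based) of lexicographically sorted key rows."""
    n = sorted_keys.shape[1]
    new = np.zeros(n, dtype=np.int64)
    new[1:] = (sorted_keys[:, 1:] != sorted_keys[:, :-1]).any(axis=0)
    return np.cumsum(new)


def bwt_from_sa(text: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """``W[i] = text[(SA[i]-1) mod n]``."""
    text = np.asarray(text, dtype=np.uint8)
    return text[(np.asarray(sa) - 1) % len(text)]


def split_bwt(w: np.ndarray):
    """Stable split of W into (U, Wl, Wr) by alphabet membership."""
    w = np.asarray(w, dtype=np.uint8)
    if (w >= NSYM).any():
        raise ValueError("symbol outside the alphabet")
    u = IS_POLY[w]
    return u, w[~u], w[u]


def counts_table(text: np.ndarray) -> np.ndarray:
    """C[c] = number of symbols lexicographically smaller than c; the extra
    final entry is the text length."""
    hist = np.bincount(np.asarray(text, dtype=np.uint8), minlength=NSYM)
    return np.concatenate([[0], np.cumsum(hist)]).astype(np.int64)


@dataclass
class BWTParts:
    W: np.ndarray
    U: np.ndarray   # boolean
    Wl: np.ndarray
    Wr: np.ndarray


class PanalnIndex:
    """Queryable pangenome index over ``full_text = T + revcomp(T) + '$'``."""

    def __init__(self, w, ann: AnnotationTable, t_len: int, context_k: int,
                 sa, sa_step: int = DEFAULT_SA_STEP):
        self.W = np.asarray(w, dtype=np.uint8)
        self.n = len(self.W)
        u_bits, wl, wr = split_bwt(self.W)
        self.parts = BWTParts(self.W, u_bits, wl, wr)
        self.U = RankBitvector(u_bits)
        self.wt_l = WaveletTree(wl, UNIQ_CODES, shape="balanced")
        self.wt_r = WaveletTree(wr, POLY_CODES, shape="huffman")
        self.C = counts_table(self.W)
        self.ann = ann
        self.t_len = t_len
        self.context_k = context_k
        self.sa_step = sa_step

        sa = np.asarray(sa, dtype=np.int64)
        marks = sa % sa_step == 0
        self.sa_marks = RankBitvector(marks)
        self.sa_samples = sa[marks]
        isa_idx = np.flatnonzero(np.arange(self.n) % sa_step == 0)
        inv = np.empty(self.n, dtype=np.int64)
        inv[sa] = np.arange(self.n)
        self.isa_samples = inv[isa_idx]

    # -- construction ------------------------------------------------------

    @classmethod
    def build(cls, pg: PangenomeText, sa_step: int = DEFAULT_SA_STEP):
        sa = build_suffix_array(pg.full_text)
        w = bwt_from_sa(pg.full_text, sa)
        return cls(w, pg.ann, pg.t_len, pg.context_k, sa, sa_step)

    @classmethod
    def build_from_text(cls, text: str, sa_step: int = DEFAULT_SA_STEP,
                        context_k: int = 0):
        """Index a raw symbol string directly (appending '$' if absent).

        Used for worked examples and differential tests where no genome/VCF
        pipeline or reverse-complement half is wanted; Ann gets one covering
        record.
        """
        from .pangenome import AnnRecord, BACKBONE
        if not text.endswith("$"):
            text = text + "$"
        codes = iupac.encode(text)
        t_len = len(text) - 1
        ann = AnnotationTable(
            [AnnRecord(0, t_len, 0, BACKBONE, 0, 0, 0, 0)], ["seq"], [t_len]
        )
        sa = build_suffix_array(codes)
        w = bwt_from_sa(codes, sa)
        idx = cls(w, ann, t_len, context_k, sa, sa_step)
        idx.single_strand = True
        return idx

    # -- Occ / LF ----------------------------------------------------------

    def occ_batch_excl(self, pos_excl: np.ndarray, codes) -> dict:
        """Counts of each code strictly before each position (vectorised).

        The routing rank on U is done once for the whole position array, and
        each wavelet-tree node on a queried path is ranked once.
        """
        pos_excl = np.asarray(pos_excl, dtype=np.int64)
        ones = self.U._rank_excl(pos_excl)
        out = {}
        uniq = [c for c in codes if not IS_POLY[c]]
        poly = [c for c in codes if IS_POLY[c]]
        if uniq:
            out.update(self.wt_l.occ_batch(pos_excl - ones, uniq))
        if poly:
            out.update(self.wt_r.occ_batch(ones, poly))
        return out

    def occ_c(self, i: int, c: int) -> int:
        """Occurrences of code c in ``W[0..i]`` (inclusive; i = -1 gives 0)."""
        if not 0 <= c < NSYM:
            raise ValueError(f"symbol code {c} outside the alphabet")
        if not -1 <= i < self.n:
            raise IndexError("occ position out of range")
        return int(self.occ_batch_excl(np.array([i + 1]), (c,))[c][0])

    def occ_batch(self, i: int, codes) -> dict:
        """Inclusive batched Occ for a symbol set at one position."""
        if len(codes) == 0:
            raise ValueError("empty symbol set")
        res = self.occ_batch_excl(np.array([i + 1]), tuple(codes))
        return {c: int(v[0]) for c, v in res.items()}

    def lf(self, c: int, i: int) -> int:
        """``LF(c, i) = C[c] + Occ_c(W, i)``."""
        return int(self.C[c]) + self.occ_c(i, c)

    def lf_step(self, row: int) -> int:
        """Row of the suffix one position to the left: ``SA -> SA - 1``."""
        c = int(self.W[row])
        return int(self.C[c]) + self.occ_c(row - 1, c)

    # -- flattened view for the compiled inner loops -------------------------

    @property
    def flat(self):
        """Arrays consumed by the numba kernels (built lazily, cached)."""
        if getattr(self, "_flat", None) is None:
            from .iupac import BASE_INDEX, GAMMA_CODES, IS_POLY
            poly_mask = 0
            for c in np.flatnonzero(IS_POLY):
                poly_mask |= 1 << int(c)
            gamma = np.zeros((4, 7), dtype=np.int64)
            glen = np.zeros(4, dtype=np.int64)
            for b, bi in BASE_INDEX.items():
                cs = GAMMA_CODES[b]
                gamma[bi, : len(cs)] = cs
                glen[bi] = len(cs)
            self._gamma, self._glen = gamma, glen
            self._flat = (
                self.C,
                np.int64(poly_mask),
                self.U.words,
                _abs_wcum(self.U),
                *_flatten_tree(self.wt_l),
                *_flatten_tree(self.wt_r),
            )
            self._marks_flat = (
                self.sa_marks.words,
                _abs_wcum(self.sa_marks),
                self.sa_samples,
            )
        return self._flat

    # -- locate / extract support ------------------------------------------

    def sa_lookup(self, row: int) -> int:
        """Text position of the suffix at ``row`` via the sampled SA."""
        from ._kernels import sa_lookup_kernel
        f = self.flat
        return int(sa_lookup_kernel(np.int64(row), self.W, *f, *self._marks_flat))

    def sa_lookup_py(self, row: int) -> int:
        """Uncompiled reference walk (differentially tested vs sa_lookup)."""
        steps = 0
        while not self.sa_marks.get(row):
            row = self.lf_step(row)
            steps += 1
        base = int(self.sa_samples[self.sa_marks.rank1(row) - 1])
        return base + steps

    def extract_codes(self, pos: int, length: int) -> np.ndarray:
        """``full_text[pos .. pos+length-1]`` reconstructed by LF-walking
        from the nearest inverse-SA sample past the end of the span."""
        if length < 0 or pos < 0 or pos + length > self.n:
            raise IndexError("extract range out of bounds")
        if length == 0:
            return np.empty(0, dtype=np.uint8)
        end = pos + length
        out_tail = 0
        if end == self.n:  # the sentinel is always the last symbol
            out_tail = 1
            end -= 1
            if length == out_tail:
                return np.array([SENTINEL], dtype=np.uint8)
        j0 = -(-end // self.sa_step) * self.sa_step  # first sample >= end
        if j0 >= self.n:
            row, j = 0, self.n - 1  # row 0 holds the suffix at position n-1
        else:
            row, j = int(self.isa_samples[j0 // self.sa_step]), j0
        from ._kernels import extract_kernel
        return extract_kernel(
            np.int64(pos), np.int64(length), np.int64(end),
            np.int64(row), np.int64(j), out_tail == 1,
            self.W, *self.flat,
        )

    # -- serialization ------------------------------------------------------

    def serialize(self, path: str) -> None:
        arrays = {
            "W": self.W,
            "sa_samples": self.sa_samples,
            "isa_samples": self.isa_samples,
            "ann": self.ann.to_arrays(),
            "chrom_lengths": np.asarray(self.ann.chrom_lengths, dtype=np.int64),
        }
        meta = {
            "symbol_order": SYMBOL_ORDER,
            "t_len": self.t_len,
            "context_k": self.context_k,
            "sa_step": self.sa_step,
            "chrom_names": self.ann.chrom_names,
            "single_strand": bool(getattr(self, "single_strand", False)),
            "huffman_code_lengths": {
                str(k): v for k, v in self.wt_r.code_lengths.items()
            },
            "sections": [],
        }
        blobs = []
        off = 0
        for name, arr in arrays.items():
            raw = np.ascontiguousarray(arr).tobytes()
            meta["sections"].append(
                {"name": name, "dtype": str(arr.dtype),
                 "shape": list(arr.shape), "offset": off, "size": len(raw)}
            )
            blobs.append(raw)
            off += len(raw)
        header = json.dumps(meta).encode()
        with open(path, "wb") as fh:
            fh.write(MAGIC)
            fh.write(VERSION.to_bytes(4, "little"))
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            for b in blobs:
                fh.write(b)

    @classmethod
    def deserialize(cls, path: str) -> "PanalnIndex":
        with open(path, "rb") as fh:
            data = fh.read()
        if data[: len(MAGIC)] != MAGIC:
            raise IndexFormatError("not a panaln index (bad magic)")
        ver = int.from_bytes(data[12:16], "little")
        if ver != VERSION:
            raise IndexFormatError(f"unsupported index version {ver}")
        hlen = int.from_bytes(data[16:24], "little")
        try:
            meta = json.loads(data[24:24 + hlen].decode())
            body = data[24 + hlen:]
            arrays = {}
            for sec in meta["sections"]:
                raw = body[sec["offset"]: sec["offset"] + sec["size"]]
                if len(raw) != sec["size"]:
                    raise IndexFormatError("truncated index file")
                arrays[sec["name"]] = np.frombuffer(
                    raw, dtype=np.dtype(sec["dtype"])
                ).reshape(sec["shape"])
        except IndexFormatError:
            raise
        except Exception as exc:
            raise IndexFormatError(f"corrupt index file: {exc}") from exc
        if meta["symbol_order"] != SYMBOL_ORDER:
            raise IndexFormatError("index built with a different symbol order")
        ann = AnnotationTable.from_arrays(
            arrays["ann"], meta["chrom_names"],
            [int(x) for x in arrays["chrom_lengths"]],
        )
        idx = cls.__new__(cls)
        w = arrays["W"].astype(np.uint8)
        idx.W = w
        idx.n = len(w)
        u_bits, wl, wr = split_bwt(w)
        idx.parts = BWTParts(w, u_bits, wl, wr)
        idx.U = RankBitvector(u_bits)
        idx.wt_l = WaveletTree(wl, UNIQ_CODES, shape="balanced")
        idx.wt_r = WaveletTree(wr, POLY_CODES, shape="huffman")
        stored = {int(k): v for k, v in meta["huffman_code_lengths"].items()}
        if stored != idx.wt_r.code_lengths:
            raise IndexFormatError("Huffman code table mismatch")
        idx.C = counts_table(w)
        idx.ann = ann
        idx.t_len = meta["t_len"]
        idx.context_k = meta["context_k"]
        idx.sa_step = meta["sa_step"]
        idx.sa_samples = arrays["sa_samples"].astype(np.int64)
        idx.isa_samples = arrays["isa_samples"].astype(np.int64)
        if meta.get("single_strand"):
            idx.single_strand = True
        # rebuild the SA-mark bitvector by one backward pass over the BWT
        idx.sa_marks = _rebuild_marks(idx)
        return idx


def _abs_wcum(bv: RankBitvector) -> np.ndarray:
    """Absolute exclusive one-count per packed word (kernel rank support)."""
    wpop = np.bitwise_count(bv.words).astype(np.int64)
    return np.concatenate(([0], np.cumsum(wpop)[:-1]))


def _flatten_tree(wt):
    """Preorder-flattened wavelet tree arrays for the compiled descent:
    (left, right, rmask, words, wcum, woff)."""
    left, right, rmask, woff = [], [], [], []
    words_parts, wcum_parts = [], []
    off = 0

    def visit(node):
        nonlocal off
        my = len(left)
        left.append(-1)
        right.append(-1)
        rmask.append(0)
        woff.append(0)
        if node.is_leaf:
            return my
        m = 0
        for c in node.right_set:
            m |= 1 << int(c)
        rmask[my] = m
        woff[my] = off
        words_parts.append(node.bv.words)
        wpop = np.bitwise_count(node.bv.words).astype(np.int64)
        wcum_parts.append(np.concatenate(([0], np.cumsum(wpop)[:-1])))
        off += len(node.bv.words)
        left[my] = visit(node.left)
        right[my] = visit(node.right)
        return my

    visit(wt.root)
    words = (
        np.concatenate(words_parts) if words_parts
        else np.zeros(1, dtype=np.uint64)
    )
    wcum = (
        np.concatenate(wcum_parts) if wcum_parts
        else np.zeros(1, dtype=np.int64)
    )
    return (
        np.array(left, dtype=np.int64),
        np.array(right, dtype=np.int64),
        np.array(rmask, dtype=np.int64),
        words,
        wcum,
        np.array(woff, dtype=np.int64),
    )


def _rebuild_marks(idx: PanalnIndex) -> RankBitvector:
    """Recover which rows are SA-sampled by inverting the BWT once."""
    lf = np.empty(idx.n, dtype=np.int64)
    for c in np.unique(idx.W):
        where = np.flatnonzero(idx.W == c)
        lf[where] = idx.C[c] + np.arange(len(where))
    marks = np.zeros(idx.n, dtype=bool)
    row = 0  # '$' row holds the suffix starting at the last position
    for pos in range(idx.n - 1, -1, -1):
        if pos % idx.sa_step == 0:
            marks[row] = True
        row = lf[row]
    return RankBitvector(marks)
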