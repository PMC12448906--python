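"""Succinct rank support over a plain bitvector.

Bits are packed into 64-bit words.  Cumulative one-counts are kept at three
levels: superblocks of 2**16 bits store absolute counts, 512-bit blocks
store counts relative to their superblock, and each word stores its offset
within the block, so a rank query is three table lookups plus a single
masked popcount.  Queries accept position arrays and are fully vectorised.
"""

from __future__ import annotations

import numpy as np

SUPERBLOCK_BITS = 1 << 16
BLOCK_BITS = 512


class RankBitvector:
    """Bit string with O(1) ``rank1`` (number of ones in a prefix)."""

    def __init__(self, bits: np.ndarray):
        bits = np.asarray(bits, dtype=bool)
        self.n = len(bits)
        nwords = (self.n + 63) // 64 + 1  # one zero pad word for pos == n
        padded = np.zeros(nwords * 64, dtype=bool)
        padded[: self.n] = bits
        # bit j of word w is position 64*w + j
        self.words = np.packbits(
            padded.reshape(nwords, 8, 8)[:, :, ::-1]
        ).view(np.uint64)
        wpop = np.bitwise_count(self.words).astype(np.int64)
        abs_before = np.concatenate(([0], np.cumsum(wpop)[:-1]))
        self.total_ones = int(abs_before[-1] + wpop[-1])

        wpb = BLOCK_BITS // 64
        wps = SUPERBLOCK_BITS // 64
        self.super_counts = abs_before[::wps].copy()            # absolute
        blk_abs = abs_before[::wpb]
        sb_of_block = np.arange(len(blk_abs)) // (wps // wpb)
        self.block_counts = (
            blk_abs - self.super_counts[sb_of_block]
        ).astype(np.uint32)                                     # relative to superblock
        self.word_counts = (
            abs_before - blk_abs[np.arange(nwords) // wpb]
        ).astype(np.uint16)                                     # relative to block

    def __len__(self) -> int:
        return self.n

    # -- queries -----------------------------------------------------------

    def rank1(self, i):
        """Number of ones in ``B[0..i]`` inclusive; ``i = -1`` gives 0.

        Accepts a scalar or an integer array (element-wise query).
        """
        if np.isscalar(i):
            if not -1 <= i < self.n:
                raise IndexError("rank position out of range")
            return self.rank_excl_one(i + 1)
        pos = np.asarray(i, dtype=np.int64) + 1
        if len(pos) and ((pos < 0).any() or (pos > self.n).any()):
            raise IndexError("rank position out of range")
        return self._rank_excl(pos)

    def _rank_excl(self, pos: np.ndarray) -> np.ndarray:
        """Ones strictly before ``pos`` (0 <= pos <= n), vectorised."""
        pos = np.asarray(pos, dtype=np.int64)
        w = pos >> 6
        mask = (np.uint64(1) << (pos & 63).astype(np.uint64)) - np.uint64(1)
        return (
            self.super_counts[pos >> 16]
            + self.block_counts[pos >> 9]
            + self.word_counts[w]
            + np.bitwise_count(self.words[w] & mask).astype(np.int64)
        )

    def rank_excl_one(self, pos: int) -> int:
        """Scalar fast path of :meth:`_rank_excl`."""
        w = pos >> 6
        r = pos & 63
        part = int(self.words[w]) & ((1 << r) - 1)
        return (
            int(self.super_counts[pos >> 16])
            + int(self.block_counts[pos >> 9])
            + int(self.word_counts[w])
            + part.bit_count()
        )

    def get(self, i):
        """Bit at position i (scalar or array)."""
        i = np.asarray(i, dtype=np.int64)
        return (self.words[i >> 6] >> (i & 63).astype(np.uint64)) & np.uint64(1)
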