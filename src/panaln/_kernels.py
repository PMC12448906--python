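"""Compiled inner loops for the alignment path.

The class-based structures in :mod:`bitvector`, :mod:`wavelet` and
:mod:`fmindex` define the index semantics and are what the public Occ/LF
API uses.  The read-mapping loop, however, performs millions of tiny rank
queries, so the interval-stepping, D-array and LF-walk loops are compiled
with numba over a flattened view of the same structures.  Kernel results
are differentially tested against the class-based path; both are checked
against naive scans.
"""

from __future__ import annotations

import numpy as np
from numba import njit

U1 = np.uint64(1)
M1 = np.uint64(0x5555555555555555)
M2 = np.uint64(0x3333333333333333)
M4 = np.uint64(0x0F0F0F0F0F0F0F0F)
H01 = np.uint64(0x0101010101010101)

#: capacity of the interval-set work buffers (cap * max gamma-set size)
BUF = 64 * 7 + 8


@njit(cache=True, inline="always")
def _popcount64(x):
    x = x - ((x >> U1) & M1)
    x = (x & M2) + ((x >> np.uint64(2)) & M2)
    x = (x + (x >> np.uint64(4))) & M4
    return np.int64((x * H01) >> np.uint64(56))


@njit(cache=True, inline="always")
def _rank_excl(words, wcum, base, pos):
    w = base + (pos >> 6)
    r = pos & 63
    if r == 0:
        return wcum[w]
    mask = (U1 << np.uint64(r)) - U1
    return wcum[w] + _popcount64(words[w] & mask)


@njit(cache=True, inline="always")
def _occ_tree(p, code, left, right, rmask, words, wcum, woff):
    node = 0
    while left[node] >= 0:
        ones = _rank_excl(words, wcum, woff[node], p)
        if (rmask[node] >> code) & 1:
            p = ones
            node = right[node]
        else:
            p = p - ones
            node = left[node]
    return p


@njit(cache=True)
def _step(lo, hi, m, codes,
          C, poly_mask,
          u_words, u_wcum,
          lL, rL, mL, wL, cL, oL,
          lR, rR, mR, wR, cR, oR,
          out_lo, out_hi):
    cnt = 0
    for k in range(m):
        p0 = lo[k]
        p1 = hi[k] + 1
        o0 = _rank_excl(u_words, u_wcum, 0, p0)
        o1 = _rank_excl(u_words, u_wcum, 0, p1)
        for ci in range(len(codes)):
            c = codes[ci]
            if (poly_mask >> c) & 1:
                a = _occ_tree(o0, c, lR, rR, mR, wR, cR, oR)
                b = _occ_tree(o1, c, lR, rR, mR, wR, cR, oR)
            else:
                a = _occ_tree(p0 - o0, c, lL, rL, mL, wL, cL, oL)
                b = _occ_tree(p1 - o1, c, lL, rL, mL, wL, cL, oL)
            nl = C[c] + a
            nh = C[c] + b - 1
            if nl <= nh:
                out_lo[cnt] = nl
                out_hi[cnt] = nh
                cnt += 1
    return cnt


@njit(cache=True)
def _merge_cap(out_lo, out_hi, cnt, lo, hi, cap):
    """Sort result intervals, fuse adjacent ones, keep the widest ``cap``.

    Result intervals are pairwise disjoint by construction (distinct symbol
    blocks / disjoint parents), so fusing only joins touching neighbours.
    Returns (m, truncated).
    """
    if cnt == 0:
        return 0, False
    order = np.argsort(out_lo[:cnt])
    m = 0
    for ii in range(cnt):
        i = order[ii]
        if m > 0 and out_lo[i] <= hi[m - 1] + 1:
            if out_hi[i] > hi[m - 1]:
                hi[m - 1] = out_hi[i]
        else:
            lo[m] = out_lo[i]
            hi[m] = out_hi[i]
            m += 1
    if m <= cap:
        return m, False
    widths = hi[:m] - lo[:m]
    thr_idx = np.argsort(widths)[m - cap]
    thr = widths[thr_idx]
    # keep intervals wider than thr, then fill with == thr up to cap
    keep = 0
    for i in range(m):
        if widths[i] > thr:
            lo[keep] = lo[i]
            hi[keep] = hi[i]
            widths[keep] = widths[i]
            keep += 1
    for i in range(m):
        if keep >= cap:
            break
        w = hi[i] - lo[i]
        if w == thr:
            lo[keep] = lo[i]
            hi[keep] = hi[i]
            keep += 1
    # restore sorted order
    order2 = np.argsort(lo[:keep])
    tl = lo[:keep][order2].copy()
    th = hi[:keep][order2].copy()
    lo[:keep] = tl
    hi[:keep] = th
    return keep, True


@njit(cache=True)
def d_array_kernel(qcomp, n, gamma, glen, cap,
                   C, poly_mask, u_words, u_wcum,
                   lL, rL, mL, wL, cL, oL,
                   lR, rR, mR, wR, cR, oR):
    """D array: qcomp holds complemented read bases as 0..3 (-1 for N)."""
    d = np.empty(len(qcomp), dtype=np.int32)
    lo = np.empty(BUF, dtype=np.int64)
    hi = np.empty(BUF, dtype=np.int64)
    out_lo = np.empty(BUF, dtype=np.int64)
    out_hi = np.empty(BUF, dtype=np.int64)
    m = 1
    lo[0] = 0
    hi[0] = n - 1
    z = 0
    for i in range(len(qcomp)):
        b = qcomp[i]
        cnt = 0
        if b >= 0:
            cnt = _step(lo, hi, m, gamma[b, :glen[b]],
                        C, poly_mask, u_words, u_wcum,
                        lL, rL, mL, wL, cL, oL,
                        lR, rR, mR, wR, cR, oR,
                        out_lo, out_hi)
        if cnt == 0:
            z += 1
            m = 1
            lo[0] = 0
            hi[0] = n - 1
        else:
            m, _ = _merge_cap(out_lo, out_hi, cnt, lo, hi, cap)
        d[i] = z
    return d


@njit(cache=True)
def count_kernel(pat, n, gamma, glen, cap,
                 C, poly_mask, u_words, u_wcum,
                 lL, rL, mL, wL, cL, oL,
                 lR, rR, mR, wR, cR, oR):
    """Backward search; pat holds read bases 0..3 (-1 for N), in read order.

    Returns (lo, hi, m, truncated)."""
    lo = np.empty(BUF, dtype=np.int64)
    hi = np.empty(BUF, dtype=np.int64)
    out_lo = np.empty(BUF, dtype=np.int64)
    out_hi = np.empty(BUF, dtype=np.int64)
    m = 1
    lo[0] = 0
    hi[0] = n - 1
    truncated = False
    for i in range(len(pat) - 1, -1, -1):
        b = pat[i]
        cnt = 0
        if b >= 0:
            cnt = _step(lo, hi, m, gamma[b, :glen[b]],
                        C, poly_mask, u_words, u_wcum,
                        lL, rL, mL, wL, cL, oL,
                        lR, rR, mR, wR, cR, oR,
                        out_lo, out_hi)
        if cnt == 0:
            return lo[:0], hi[:0], 0, truncated
        m, t = _merge_cap(out_lo, out_hi, cnt, lo, hi, cap)
        truncated = truncated or t
    return lo[:m].copy(), hi[:m].copy(), m, truncated


@njit(cache=True, inline="always")
def _lf_step(row, W, C, poly_mask, u_words, u_wcum,
             lL, rL, mL, wL, cL, oL,
             lR, rR, mR, wR, cR, oR):
    c = np.int64(W[row])
    ones = _rank_excl(u_words, u_wcum, 0, row)
    if (poly_mask >> c) & 1:
        occ = _occ_tree(ones, c, lR, rR, mR, wR, cR, oR)
    else:
        occ = _occ_tree(row - ones, c, lL, rL, mL, wL, cL, oL)
    return C[c] + occ


@njit(cache=True)
def sa_lookup_kernel(row, W, C, poly_mask, u_words, u_wcum,
                     lL, rL, mL, wL, cL, oL,
                     lR, rR, mR, wR, cR, oR,
                     mark_words, mark_wcum, sa_samples):
    steps = 0
    while ((mark_words[row >> 6] >> np.uint64(row & 63)) & U1) == 0:
        row = _lf_step(row, W, C, poly_mask, u_words, u_wcum,
                       lL, rL, mL, wL, cL, oL,
                       lR, rR, mR, wR, cR, oR)
        steps += 1
    r = _rank_excl(mark_words, mark_wcum, 0, row)
    return sa_samples[r] + steps


@njit(cache=True)
def extract_kernel(pos, length, end, start_row, start_j, sentinel_tail,
                   W, C, poly_mask, u_words, u_wcum,
                   lL, rL, mL, wL, cL, oL,
                   lR, rR, mR, wR, cR, oR):
    out = np.empty(length, dtype=np.uint8)
    if sentinel_tail:
        out[length - 1] = 0  # '$' code
    row = start_row
    j = start_j
    while j > pos:
        sym = W[row]
        j -= 1
        if j < end:
            out[j - pos] = sym
        row = _lf_step(row, W, C, poly_mask, u_words, u_wcum,
                       lL, rL, mL, wL, cL, oL,
                       lR, rR, mR, wR, cR, oR)
    return out
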