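"""Gap-affine wavefront alignment with IUPAC-inclusive matching.

Minimum-cost pairwise alignment of a plain DNA read against a pangenome
window that may contain IUPAC symbols: read base ``g`` matches window symbol
``s`` at cost zero iff ``s`` is in the compatibility class of ``g`` (so
``TAA`` aligns to ``TWA`` for free), otherwise the mismatch penalty applies.
Wavefronts of furthest-reaching points are advanced score by score --
the classic character-equality test of the extend step is replaced by the
inclusive compatibility test -- giving O(n*s) time in sequence length n and
alignment cost s.

Two modes: *global* (both sequences end to end) and *text-ends-free*, where
leading/trailing window symbols may be skipped at no cost; the read is
always consumed end to end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .iupac import BASE_INDEX, COMPAT, encode

NEG = -(10 ** 9)


@dataclass(frozen=True)
class Penalties:
    """Non-negative integer costs; match is free.  A length-L gap costs
    ``gap_open + L * gap_extend``."""

    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 2

    def __post_init__(self):
        if min(self.mismatch, self.gap_open, self.gap_extend) < 0:
            raise ValueError("penalties must be non-negative")
        if self.mismatch == 0 or self.gap_open + self.gap_extend == 0:
            raise ValueError("mismatch and gap costs must be positive")


@dataclass
class WFAResult:
    score: int
    cigar: str             # read-oriented: M consumes both, I read-only, D text-only
    text_start: int        # first window position consumed by the alignment
    text_end: int          # one past the last window position consumed


def _compat_row(read: str) -> np.ndarray:
    """(|read|, NSYM) boolean compatibility matrix; 'N' matches nothing."""
    rows = np.zeros((len(read), COMPAT.shape[1]), dtype=bool)
    for i, b in enumerate(read):
        bi = BASE_INDEX.get(b.upper())
        if bi is not None:
            rows[i] = COMPAT[bi]
    return rows


def wfa_align(read: str, window, pen: Penalties = Penalties(),
              text_ends_free: bool = False,
              max_score: int | None = None) -> WFAResult | None:
    """Minimum-cost gap-affine alignment of ``read`` against ``window``.

    ``window`` may be a symbol string or a uint8 code array.  Returns None
    only when ``max_score`` is given and exceeded.
    """
    if isinstance(window, str):
        window = encode(window)
    window = np.asarray(window, dtype=np.uint8)
    m, n = len(read), len(window)
    if m == 0 or n == 0:
        raise ValueError("empty sequence")
    compat = _compat_row(read)
    ok = compat[np.arange(m)[:, None], window[None, :]]  # (m, n) match matrix

    x, o, e = pen.mismatch, pen.gap_open, pen.gap_extend
    if max_score is None:
        max_score = x * m + o + e * (m + n)  # always reachable

    # wavefronts[s] = (M, I, D) dicts: diagonal k = h - v  ->  offset h
    M: dict = {}
    I: dict = {}
    D: dict = {}

    def extend(d):
        for k, h in d.items():
            v = h - k
            while v < m and h < n and ok[v, h]:
                v += 1
                h += 1
            d[k] = h

    m0 = {}
    if text_ends_free:
        for k in range(0, n + 1):  # any leading-text skip is free
            m0[k] = k
    else:
        m0[0] = 0
    extend(m0)
    M[0] = m0
    I[0] = {}
    D[0] = {}

    def done(s):
        ks = sorted(M[s])
        for k in ks:
            h = M[s][k]
            if h - k == m and (text_ends_free or h == n):
                return k
        return None

    end_k = done(0)
    s = 0
    while end_k is None:
        s += 1
        if s > max_score:
            return None
        mi, ii, di = {}, {}, {}
        src_open = M.get(s - o - e, {})
        src_iext = I.get(s - e, {})
        src_dext = D.get(s - e, {})
        src_mm = M.get(s - x, {})
        ks = set()
        for k in src_open:
            ks.add(k + 1)
            ks.add(k - 1)
        ks.update(k + 1 for k in src_iext)
        ks.update(k - 1 for k in src_dext)
        ks.update(src_mm)
        for k in ks:
            ih = max(src_open.get(k - 1, NEG), src_iext.get(k - 1, NEG)) + 1
            dh = max(src_open.get(k + 1, NEG), src_dext.get(k + 1, NEG))
            if 0 <= ih <= n and ih - k <= m:
                ii[k] = ih
            if dh >= 0 and dh - k <= m:
                di[k] = dh
            best = max(src_mm.get(k, NEG) + 1, ii.get(k, NEG), di.get(k, NEG))
            if 0 <= best <= n and best - k <= m:
                mi[k] = best
        extend(mi)
        # keep only in-bound points
        mi = {k: h for k, h in mi.items() if h <= n and 0 <= h - k <= m}
        M[s], I[s], D[s] = mi, ii, di
        end_k = done(s)

    return _traceback(M, I, D, s, end_k, ok, pen, text_ends_free)


def _traceback(M, I, D, s, k, ok, pen, ends_free) -> WFAResult:
    x, o, e = pen.mismatch, pen.gap_open, pen.gap_extend
    score = s
    h = M[s][k]
    text_end = h
    ops = []  # appended in reverse alignment order
    comp = "M"
    text_start = 0
    while True:
        if comp == "M":
            h0 = k if (ends_free and k > 0) else 0
            if s == 0 and h == h0:
                text_start = h0
                break
            if I.get(s, {}).get(k) == h:
                comp = "I"
            elif D.get(s, {}).get(k) == h:
                comp = "D"
            elif s >= x and M.get(s - x, {}).get(k, NEG) + 1 == h:
                ops.append(("M", 1))  # mismatch consumes both
                s -= x
                h -= 1
            else:
                ops.append(("M", 1))  # free match
                h -= 1
        elif comp == "I":  # text-consuming gap: SAM 'D'
            ext = I.get(s - e, {}).get(k - 1, NEG) + 1
            ops.append(("D", 1))
            h -= 1
            k -= 1
            if ext == h + 1:
                s -= e
            else:
                s -= o + e
                comp = "M"
        else:  # query-consuming gap: SAM 'I'
            ext = D.get(s - e, {}).get(k + 1, NEG)
            ops.append(("I", 1))
            k += 1
            if ext == h:
                s -= e
            else:
                s -= o + e
                comp = "M"

    # merge runs into a CIGAR string
    cig = []
    for op, ln in reversed(ops):
        if cig and cig[-1][0] == op:
            cig[-1][1] += ln
        else:
            cig.append([op, ln])
    cigar = "".join(f"{ln}{op}" for op, ln in cig)
    return WFAResult(score=score, cigar=cigar, text_start=text_start,
                     text_end=text_end)
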