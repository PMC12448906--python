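"""Independent brute-force oracles used to validate the index and aligner.

Everything here deliberately avoids the package's FM-index/wavefront code
paths: occurrence counting scans the text directly, the D array follows its
definition with an online candidate filter, and pairwise alignment is a
Gotoh dynamic program.
"""

import numpy as np

from panaln.iupac import BASE_INDEX, COMPAT, encode


def naive_sa(codes):
    codes = np.asarray(codes, dtype=np.uint8)
    return sorted(range(len(codes)), key=lambda i: list(codes[i:]))


def compat_positions(text_codes, pattern):
    """Start positions where the DNA pattern is IUPAC-compatible."""
    text_codes = np.asarray(text_codes, dtype=np.uint8)
    n, L = len(text_codes), len(pattern)
    if L == 0 or L > n:
        return np.empty(0, dtype=np.int64)
    ok = np.ones(n - L + 1, dtype=bool)
    for j, b in enumerate(pattern):
        bi = BASE_INDEX.get(b)
        col = (
            COMPAT[bi, text_codes[j: n - L + 1 + j]]
            if bi is not None
            else np.zeros(n - L + 1, dtype=bool)
        )
        ok &= col
    return np.flatnonzero(ok)


def compat_count(text_codes, pattern):
    return len(compat_positions(text_codes, pattern))


def d_array_definitional(full_text_codes, q):
    """D by definition: grow the substring until it stops occurring.

    Keeps the set of candidate start positions of the current substring and
    filters it as each base is appended (online matcher; no index involved).
    """
    text = np.asarray(full_text_codes, dtype=np.uint8)
    n = len(text)
    d = np.empty(len(q), dtype=np.int32)
    z = 0
    cand = None  # start positions matching the current substring
    cur_len = 0
    for i, b in enumerate(q):
        bi = BASE_INDEX.get(b)
        if bi is None:
            new = np.empty(0, dtype=np.int64)
        elif cand is None:
            new = np.flatnonzero(COMPAT[bi, text])
        else:
            ends = cand + cur_len
            keep = ends < n
            c = cand[keep]
            new = c[COMPAT[bi, text[c + cur_len]]]
        if len(new) == 0:
            z += 1
            cand = None
            cur_len = 0
        else:
            cand = new
            cur_len += 1
        d[i] = z
    return d


def gotoh_score(read, window, pen, ends_free=False):
    """Min-cost gap-affine alignment score (vectorised row DP).

    A length-L gap costs ``gap_open + L * gap_extend``; read base vs window
    symbol is free iff IUPAC-compatible.  ``ends_free`` leaves leading and
    trailing *window* symbols unpenalised; the read is global.
    """
    x, o, e = pen.mismatch, pen.gap_open, pen.gap_extend
    w = encode(window) if isinstance(window, str) else np.asarray(window)
    m, n = len(read), len(w)
    INF = 10 ** 9
    sub = np.empty((m, n), dtype=np.int64)
    for i, b in enumerate(read):
        bi = BASE_INDEX.get(b)
        sub[i] = np.where(COMPAT[bi, w], 0, x) if bi is not None else x

    M = np.full(n + 1, INF, dtype=np.int64)
    Ix = np.full(n + 1, INF, dtype=np.int64)   # gap consuming window
    Iy = np.full(n + 1, INF, dtype=np.int64)   # gap consuming read
    M[0] = 0
    if ends_free:
        M[1:] = 0
    else:
        Ix[1:] = o + e * np.arange(1, n + 1)
    for i in range(1, m + 1):
        prev_best = np.minimum(np.minimum(M, Ix), Iy)
        Mi = np.full(n + 1, INF, dtype=np.int64)
        Mi[1:] = prev_best[:-1] + sub[i - 1]
        Iyi = np.minimum(np.minimum(M, Ix) + o + e, Iy + e)
        # Ix_i[j] = min_{k<j} (min(Mi, Iyi)[k] + o + (j-k) e): prefix-min trick
        base = np.minimum(Mi, Iyi) + o - e * np.arange(n + 1)
        run = np.minimum.accumulate(base)
        Ixi = np.full(n + 1, INF, dtype=np.int64)
        Ixi[1:] = run[:-1] + e * np.arange(1, n + 1)
        M, Ix, Iy = Mi, Ixi, Iyi
    if ends_free:
        return int(min(np.minimum(M, Iy).min(), INF))
    return int(min(M[n], Ix[n], Iy[n]))


def gotoh_score_slow(read, window, pen, ends_free=False):
    """Scalar reference for :func:`gotoh_score` (tiny inputs only)."""
    x, o, e = pen.mismatch, pen.gap_open, pen.gap_extend
    w = encode(window)
    m, n = len(read), len(w)
    INF = 10 ** 9
    M = np.full((m + 1, n + 1), INF)
    Ix = np.full((m + 1, n + 1), INF)
    Iy = np.full((m + 1, n + 1), INF)
    M[0, 0] = 0
    for j in range(1, n + 1):
        Ix[0, j] = min(M[0, j - 1] + o + e, Ix[0, j - 1] + e)
        if ends_free:
            M[0, j] = 0
    for i in range(1, m + 1):
        Iy[i, 0] = min(M[i - 1, 0] + o + e, Iy[i - 1, 0] + e)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            bi = BASE_INDEX.get(read[i - 1])
            s = 0 if (bi is not None and COMPAT[bi, w[j - 1]]) else x
            M[i, j] = min(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = min(min(M[i, j - 1], Iy[i, j - 1]) + o + e,
                           Ix[i, j - 1] + e)
            Iy[i, j] = min(min(M[i - 1, j], Ix[i - 1, j]) + o + e,
                           Iy[i - 1, j] + e)
    if ends_free:
        return int(min(min(M[m, j], Iy[m, j]) for j in range(n + 1)))
    return int(min(M[m, n], Ix[m, n], Iy[m, n]))
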