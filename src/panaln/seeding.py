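"""Variable-length seeding via paired D arrays and equal overlapping fragments.

``D[i]`` is a lower bound on the number of differences (sequencing errors or
unknown variants) between the read prefix ``R[0..i]`` and any compatible
region of the pangenome: it counts how often the growing substring stops
occurring in the index, resetting after each failure.  Discontinuities of D
mark estimated difference positions, but only *at or after* the true locus
(the delay phenomenon).  Computing a second D array on the reverse
complement brackets each difference from the other side; cutting the read at
the merged discontinuities of both arrays yields the equal overlapping
fragments (EOFs), whose longest member -- the LEOF -- serves as the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fmindex import PanalnIndex
from .queries import IntervalSet, backward_step

_BASE_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp_read(read: str) -> str:
    """Reverse complement of a plain A/C/G/T/N read."""
    return "".join(_BASE_COMP.get(b, "N") for b in reversed(read))


def compute_d_array(index: PanalnIndex, q: str) -> np.ndarray:
    """D array of ``q`` against the (double-stranded) index.

    The substring grows on the right; since backward search prepends on the
    left, the interval set tracks the reverse complement of the current
    substring and each new base enters as its complement.  After a failure
    the count restarts from the next position (the failed base is the cut).
    """
    if len(q) == 0:
        raise ValueError("empty query")
    from ._kernels import d_array_kernel
    from .queries import MAX_INTERVALS, _base_codes
    comp = np.array([3, 2, 1, 0], dtype=np.int64)  # A<->T, C<->G
    codes = _base_codes(q)
    qcomp = np.where(codes >= 0, comp[np.maximum(codes, 0)], -1)
    f = index.flat
    return d_array_kernel(
        qcomp, np.int64(index.n), index._gamma, index._glen,
        np.int64(MAX_INTERVALS), *f,
    )


def compute_d_array_py(index: PanalnIndex, q: str) -> np.ndarray:
    """Uncompiled reference implementation of :func:`compute_d_array`."""
    if len(q) == 0:
        raise ValueError("empty query")
    d = np.empty(len(q), dtype=np.int32)
    s = IntervalSet.full(index.n)
    z = 0
    for i, base in enumerate(q):
        step = backward_step(index, s, _BASE_COMP.get(base, "N"))
        if step.is_empty():
            z += 1
            s = IntervalSet.full(index.n)
        else:
            s = step
        d[i] = z
    return d


def discontinuities(d: np.ndarray) -> np.ndarray:
    """Positions i with ``D[i] != D[i+1]``."""
    d = np.asarray(d)
    if len(d) < 1:
        raise ValueError("empty D array")
    return np.flatnonzero(d[:-1] != d[1:])


@dataclass
class EOFPartition:
    """The read partition induced by the paired D arrays."""

    d1: np.ndarray
    d2p: np.ndarray            # D2 of the reverse complement, reversed
    k1: np.ndarray             # discontinuity positions of D1
    k2: np.ndarray             # discontinuity positions of D2'
    boundaries: np.ndarray     # sorted union of K1 and K2
    fragments: list            # half-open (start, end) spans tiling the read
    leof: tuple                # the longest fragment (leftmost on ties)

    @property
    def leof_len(self) -> int:
        return self.leof[1] - self.leof[0]


def find_leof(index: PanalnIndex, read: str) -> EOFPartition:
    """Cut the read at the merged discontinuities of D1 and D2' and return
    the partition with its longest fragment."""
    d1 = compute_d_array(index, read)
    d2 = compute_d_array(index, revcomp_read(read))
    d2p = d2[::-1].copy()
    k1 = discontinuities(d1)
    k2 = discontinuities(d2p)
    boundaries = np.union1d(k1, k2)
    fragments = []
    start = 0
    for b in boundaries:
        fragments.append((start, int(b) + 1))  # a cut at i splits i | i+1
        start = int(b) + 1
    fragments.append((start, len(read)))
    leof = max(fragments, key=lambda f: f[1] - f[0])  # max is leftmost on ties
    return EOFPartition(d1, d2p, k1, k2, boundaries, fragments, leof)
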