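"""Wavelet trees with batched prefix-count (Occ) queries.

Two shapes are supported: a *balanced* tree, which splits the (sorted)
alphabet in half at every node, and a *Huffman-shaped* tree, whose topology
is the Huffman tree of the symbol frequencies so that frequent symbols sit
near the root.  Every node stores a rank-indexed bitvector recording, for
each position of the node's subsequence, whether the symbol belongs to the
right alphabet half.

``occ_batch`` answers prefix counts for a whole set of symbols and a whole
array of positions in one descent: a node shared by several queried symbols
is visited (and its bitvector ranked) exactly once.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np

from .bitvector import RankBitvector


@dataclass
class _Node:
    symbols: tuple          # alphabet codes handled by this node, sorted
    bv: RankBitvector | None = None
    left: "_Node | None" = None
    right: "_Node | None" = None
    right_set: frozenset = field(default_factory=frozenset)

    @property
    def is_leaf(self) -> bool:
        return len(self.symbols) == 1


def _balanced_split(symbols):
    half = (len(symbols) + 1) // 2
    return symbols[:half], symbols[half:]


def _huffman_shape(symbols, freqs):
    """Return nested-tuple topology of the Huffman tree over ``symbols``.

    Ties are broken by symbol order (lower code first) so the shape is
    canonical and reproducible.
    """
    heap = [(freqs[s], (s,), s) for s in symbols]
    heapq.heapify(heap)
    counter = max(symbols) + 1
    shapes = {s: s for s in symbols}
    while len(heap) > 1:
        fa, sa, ka = heapq.heappop(heap)
        fb, sb, kb = heapq.heappop(heap)
        shapes[counter] = (shapes[ka], shapes[kb])
        heapq.heappush(heap, (fa + fb, min(sa, sb), counter))
        counter += 1
    return shapes[heap[0][2]]


def _shape_symbols(shape):
    if isinstance(shape, tuple):
        out = []
        for sub in shape:
            out.extend(_shape_symbols(sub))
        return out
    return [shape]


class WaveletTree:
    """Wavelet tree over a uint8-coded sequence.

    Parameters
    ----------
    data:
        The sequence, as symbol codes.
    alphabet:
        Codes the tree must handle (a superset of the codes present is
        allowed; absent codes simply count zero).
    shape:
        ``"balanced"`` or ``"huffman"``.
    """

    def __init__(self, data: np.ndarray, alphabet, shape: str = "balanced"):
        data = np.asarray(data, dtype=np.uint8)
        if shape not in ("balanced", "huffman"):
            raise ValueError(f"unknown wavelet tree shape {shape!r}")
        self.shape = shape
        self.n = len(data)
        self.alphabet = tuple(sorted(alphabet))
        if len(self.alphabet) == 0:
            raise ValueError("empty alphabet")
        present = np.isin(data, np.array(self.alphabet, dtype=np.uint8))
        if not present.all():
            raise ValueError("sequence contains symbols outside the alphabet")
        self.rank_calls = 0  # instrumentation: bitvector ranks performed
        if shape == "huffman":
            freqs = {
                s: int((data == s).sum()) for s in self.alphabet
            }
            topo = (
                _huffman_shape(self.alphabet, freqs)
                if len(self.alphabet) > 1
                else self.alphabet[0]
            )
            self.root = self._build_shaped(data, topo)
        else:
            self.root = self._build_balanced(data, self.alphabet)
        self.code_lengths = {}
        self._collect_depths(self.root, 0)

    # -- construction -----------------------------------------------------

    def _build_balanced(self, data, symbols):
        node = _Node(symbols=tuple(symbols))
        if node.is_leaf:
            node.count = len(data)
            return node
        left_syms, right_syms = _balanced_split(symbols)
        return self._fill(node, data, left_syms, right_syms, self._build_balanced)

    def _build_shaped(self, data, topo):
        if not isinstance(topo, tuple):
            node = _Node(symbols=(topo,))
            node.count = len(data)
            return node
        left_syms = _shape_symbols(topo[0])
        right_syms = _shape_symbols(topo[1])
        node = _Node(symbols=tuple(sorted(left_syms + right_syms)))
        right_set = frozenset(right_syms)
        bits = np.isin(data, np.array(sorted(right_set), dtype=np.uint8))
        node.bv = RankBitvector(bits)
        node.right_set = right_set
        node.left = self._build_shaped(data[~bits], topo[0])
        node.right = self._build_shaped(data[bits], topo[1])
        return node

    def _fill(self, node, data, left_syms, right_syms, builder):
        right_set = frozenset(right_syms)
        bits = np.isin(data, np.array(sorted(right_set), dtype=np.uint8))
        node.bv = RankBitvector(bits)
        node.right_set = right_set
        node.left = builder(data[~bits], left_syms)
        node.right = builder(data[bits], right_syms)
        return node

    def _collect_depths(self, node, depth):
        if node.is_leaf:
            self.code_lengths[node.symbols[0]] = depth
        else:
            self._collect_depths(node.left, depth + 1)
            self._collect_depths(node.right, depth + 1)

    # -- queries ----------------------------------------------------------

    def access(self, i: int) -> int:
        """Symbol code at position i of the encoded sequence."""
        if not 0 <= i < self.n:
            raise IndexError("access out of range")
        node = self.root
        while not node.is_leaf:
            if node.bv.get(i):
                i = int(node.bv._rank_excl(np.array([i + 1]))[0]) - 1
                node = node.right
            else:
                i = i - int(node.bv._rank_excl(np.array([i + 1]))[0])
                node = node.left
        return node.symbols[0]

    def occ(self, i: int, c: int) -> int:
        """Occurrences of code ``c`` in the prefix ``[0..i]`` (inclusive)."""
        if c not in self.code_lengths:
            return 0
        return int(
            self.occ_batch(np.array([i + 1], dtype=np.int64), (c,))[(c)][0]
        )

    def occ_batch(self, pos_excl: np.ndarray, symbols) -> dict:
        """Prefix counts for every ``c`` in ``symbols`` at every position.

        ``pos_excl`` holds *exclusive* prefix lengths (count symbols strictly
        before the position).  Returns ``{code: counts array}``.  Nodes on
        shared root-to-leaf paths are ranked once for the whole batch.
        """
        pos_excl = np.asarray(pos_excl, dtype=np.int64)
        out = {}
        wanted = [c for c in symbols]
        inside = [c for c in wanted if c in self.code_lengths]
        for c in wanted:
            if c not in self.code_lengths:
                out[c] = np.zeros(len(pos_excl), dtype=np.int64)
        if inside:
            self._descend(self.root, pos_excl, frozenset(inside), out)
        return out

    def _descend(self, node, pos, want, out):
        if node.is_leaf:
            out[node.symbols[0]] = pos
            return
        self.rank_calls += 1
        ones = node.bv._rank_excl(pos)
        want_r = want & node.right_set
        want_l = want - node.right_set
        if want_l:
            self._descend(node.left, pos - ones, want_l, out)
        if want_r:
            self._descend(node.right, ones, want_r, out)
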