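"""BWT construction, split Occ routing, LF mapping, sampled SA, container."""

import random

import numpy as np
import pytest

from conftest import EXAMPLE_T, EXAMPLE_U, EXAMPLE_W, EXAMPLE_WL, EXAMPLE_WR
from oracles import naive_sa
from panaln.fmindex import (
    IndexFormatError,
    PanalnIndex,
    build_suffix_array,
    bwt_from_sa,
    counts_table,
    split_bwt,
)
from panaln.iupac import NSYM, SYMBOL_ORDER, decode, encode


class TestSuffixArrayAndBWT:
    def test_demo_string(self):
        # "panaln$" with $=0 < a < l < n < p
        lut = {"$": 0, "a": 2, "l": 3, "n": 4, "p": 5}
        codes = np.array([lut[c] for c in "panaln$"], dtype=np.uint8)
        sa = build_suffix_array(codes)
        assert sa.tolist() == [6, 3, 1, 4, 5, 2, 0]
        inv = {v: k for k, v in lut.items()}
        w = "".join(inv[c] for c in bwt_from_sa(codes, sa))
        assert w == "nnpala$"

    def test_sentinel_required(self):
        with pytest.raises(ValueError):
            build_suffix_array(encode("ACGT"))
        with pytest.raises(ValueError):
            build_suffix_array(encode("A$C$"))

    def test_single_sentinel(self):
        assert build_suffix_array(encode("$")).tolist() == [0]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force(self, seed):
        rng = random.Random(seed)
        s = "".join(rng.choice("ACGTWKYRMSBDHV#") for _ in range(200)) + "$"
        codes = encode(s)
        assert build_suffix_array(codes).tolist() == naive_sa(codes)


class TestWorkedExample:
    def test_printed_strings_reproduced(self, example_index):
        assert decode(example_index.W) == EXAMPLE_W
        assert "".join("1" if b else "0" for b in example_index.parts.U) == EXAMPLE_U
        assert decode(example_index.parts.Wl) == EXAMPLE_WL
        assert decode(example_index.parts.Wr) == EXAMPLE_WR

    def test_split_interleave_reconstructs(self, example_index):
        u, wl, wr = example_index.parts.U, example_index.parts.Wl, example_index.parts.Wr
        out = np.empty(len(u), dtype=np.uint8)
        out[~u] = wl
        out[u] = wr
        assert (out == example_index.W).all()

    def test_rank_u_printed_prefix(self, example_index):
        assert example_index.U.rank1(10) == 2  # ones in the printed U[0..10]
        assert example_index.U.rank1(len(EXAMPLE_U) - 1) == len(EXAMPLE_WR)


class TestOccLF:
    def test_printed_c_count(self, example_index):
        w = decode(example_index.W)
        c_code = SYMBOL_ORDER.index("C")
        assert example_index.occ_c(40, c_code) == w[:41].count("C")

    def test_occ_conservation(self, example_index):
        n = example_index.n
        total = sum(example_index.occ_c(n - 1, c) for c in range(NSYM))
        assert total == n

    def test_occ_bounds_and_bad_symbol(self, example_index):
        assert example_index.occ_c(-1, 3) == 0
        with pytest.raises(IndexError):
            example_index.occ_c(example_index.n, 3)
        with pytest.raises(ValueError):
            example_index.occ_c(0, 99)
        with pytest.raises(ValueError):
            example_index.occ_batch(5, ())

    def test_occ_batch_equals_singles_on_gamma_set(self, example_index):
        from panaln.iupac import GAMMA_CODES
        codes = tuple(int(c) for c in GAMMA_CODES["A"])
        got = example_index.occ_batch(40, codes)
        assert got == {c: example_index.occ_c(40, c) for c in codes}

    def test_lf_is_permutation_and_inverts_bwt(self, example_index):
        n = example_index.n
        seen = []
        row = 0
        for _ in range(n):
            seen.append(row)
            row = example_index.lf_step(row)
        assert sorted(seen) == list(range(n))
        # walking LF from '$' spells the text right to left
        text = np.empty(n, dtype=np.uint8)
        row = 0
        for pos in range(n - 1, -1, -1):
            text[pos] = example_index.W[row]
            row = example_index.lf_step(row)
        assert decode(np.roll(text, -1)) == EXAMPLE_T + "$"

    def test_lf_equals_c_plus_occ(self, example_index):
        for i in (-1, 0, 7, 40):
            for c in (0, 1, 4, 14):
                assert example_index.lf(c, i) == int(example_index.C[c]) + example_index.occ_c(i, c)


@pytest.fixture(scope="module")
def rand_case():
    rng = random.Random(99)
    s = "".join(rng.choice("ACGTWKYRMSBDHV") for _ in range(1500))
    idx = PanalnIndex.build_from_text(s, sa_step=8)
    codes = encode(s + "$")
    sa = np.array(naive_sa(codes))
    w = codes[(sa - 1) % len(codes)]
    return s, idx, sa, w


class TestRandomTextOracles:
    def test_occ_everywhere(self, rand_case):
        _, idx, _, w = rand_case
        pos = np.arange(0, len(w) + 1)
        for c in range(NSYM):
            got = idx.occ_batch_excl(pos, (c,))[c]
            assert (got == np.concatenate([[0], np.cumsum(w == c)])).all()

    def test_sa_lookup_all_rows(self, rand_case):
        _, idx, sa, _ = rand_case
        assert all(idx.sa_lookup(r) == sa[r] for r in range(len(sa)))
        # compiled and uncompiled walks agree
        assert all(idx.sa_lookup_py(r) == sa[r] for r in range(0, len(sa), 37))

    def test_sa_step_one_is_full_sa(self):
        s = "ACGTACCTGA"
        idx = PanalnIndex.build_from_text(s, sa_step=1)
        codes = encode(s + "$")
        sa = naive_sa(codes)
        assert [idx.sa_lookup(r) for r in range(len(sa))] == sa

    def test_sentinel_row_maps_to_last_position(self, rand_case):
        _, idx, _, _ = rand_case
        assert idx.sa_lookup(0) == idx.n - 1

    def test_counts_table_multiplicities(self, rand_case):
        _, idx, _, w = rand_case
        for c in range(NSYM):
            assert idx.C[c + 1] - idx.C[c] == int((w == c).sum())
        assert (np.diff(idx.C) >= 0).all()


class TestSerialization:
    def test_round_trip_preserves_queries(self, small_index, tmp_path):
        path = str(tmp_path / "x.pidx")
        small_index.serialize(path)
        back = PanalnIndex.deserialize(path)
        rng = random.Random(5)
        rows = [rng.randrange(small_index.n) for _ in range(500)]
        assert [back.sa_lookup(r) for r in rows] == \
               [small_index.sa_lookup(r) for r in rows]
        for _ in range(200):
            i = rng.randrange(small_index.n)
            c = rng.randrange(NSYM)
            assert back.occ_c(i, c) == small_index.occ_c(i, c)
        assert (back.W == small_index.W).all()
        assert back.ann.chrom_names == small_index.ann.chrom_names
        assert back.context_k == small_index.context_k

    def test_bad_magic_is_format_error(self, tmp_path):
        p = tmp_path / "bad.pidx"
        p.write_bytes(b"NOTANINDEX" + b"\x00" * 64)
        with pytest.raises(IndexFormatError):
            PanalnIndex.deserialize(str(p))

    def test_truncated_file_is_format_error(self, example_index, tmp_path):
        p = str(tmp_path / "t.pidx")
        example_index.serialize(p)
        raw = open(p, "rb").read()
        open(p, "wb").write(raw[: len(raw) // 2])
        with pytest.raises(IndexFormatError):
            PanalnIndex.deserialize(p)

    def test_missing_path_is_io_error(self):
        with pytest.raises(OSError):
            PanalnIndex.deserialize("/nonexistent/dir/x.pidx")
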