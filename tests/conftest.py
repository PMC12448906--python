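"""Shared fixtures: small synthetic pangenomes and worked-example indexes."""

import random

import numpy as np
import pytest

from panaln.fmindex import PanalnIndex
from panaln.pangenome import ReferenceGenome, VariantSet, build_pangenome

#: the published worked-example pangenome string and its index structures
EXAMPLE_T = "CCCTWACCCTAACCCYTAAC#ACCCTACCC#CCTAACCCT"
EXAMPLE_W = "TCCTTTATAW#AACCAAAA$AC#CCCCCCCCCCCYCCCCTC"
EXAMPLE_U = "00000000011000000001001000000000001000000"
EXAMPLE_WL = "TCCTTTATAAACCAAAAACCCCCCCCCCCCCCCCTC"
EXAMPLE_WR = "W#$#Y"


def random_genome(n, seed):
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


@pytest.fixture(scope="session")
def example_index():
    """Index over the printed example text (forward strand only, no RC)."""
    return PanalnIndex.build_from_text(EXAMPLE_T, sa_step=4)


@pytest.fixture(scope="session")
def small_pangenome():
    """20-kb single-chromosome pangenome with a handful of known variants."""
    seq = random_genome(20_000, seed=1234)
    ref = ReferenceGenome([("chr1", seq)])
    vs = VariantSet(
        snvs=[("chr1", 5_001, seq[5_000], ("T" if seq[5_000] != "T" else "G",)),
              ("chr1", 12_345, seq[12_344],
               ("A" if seq[12_344] != "A" else "C",))],
        indels=[
            # insertion of 5 bp after position 8000
            ("chr1", 8_000, seq[7_999], seq[7_999] + "ACGTA"),
            # deletion of 3 bp after position 15000
            ("chr1", 15_000, seq[14_999:15_003], seq[14_999]),
        ],
    )
    pg = build_pangenome(ref, vs, context_k=101)
    return ref, vs, pg


@pytest.fixture(scope="session")
def small_index(small_pangenome):
    _, _, pg = small_pangenome
    return PanalnIndex.build(pg)


@pytest.fixture(scope="session")
def plain_index():
    """Variant-free 20-kb index (both strands) for seeding/alignment tests."""
    seq = random_genome(20_000, seed=77)
    ref = ReferenceGenome([("chr1", seq)])
    pg = build_pangenome(ref, VariantSet(), context_k=101)
    return seq, PanalnIndex.build(pg)
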