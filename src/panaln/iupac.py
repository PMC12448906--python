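"""IUPAC nucleotide codes and the pangenome symbol alphabet.

A pangenome text is written over sixteen symbols: the four unique bases
``A/C/G/T`` (sigma_uniq) plus the polymorphic layer (sigma_poly) made of the
multi-base IUPAC codes, the fragment separator ``#`` and the terminal
sentinel ``$``.  The four-base code ``N`` is deliberately excluded from the
alphabet; SNP sites whose allele union would be {A,C,G,T} are truncated.

Symbols are handled internally as small integers (``uint8``) whose value is
the symbol's position in :data:`SYMBOL_ORDER`, the total order used for
suffix sorting.  ``$`` sorts strictly smallest, then ``#``, then the letters
alphabetically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Lexicographic order of the full alphabet used for suffix sorting.
SYMBOL_ORDER = "$#ABCDGHKMRSTVWY"

SIGMA_UNIQ = frozenset("ACGT")
SIGMA_POLY = frozenset("KSBYMHVRDW#$")

#: IUPAC code -> set of bases it stands for (single-base codes included).
BASES_OF_CODE = {
    "T": "T", "K": "GT", "G": "G", "S": "CG", "B": "CGT", "Y": "CT",
    "C": "C", "M": "AC", "H": "ACT", "V": "ACG", "R": "AG", "D": "AGT",
    "W": "AT", "A": "A",
}

#: Symbol -> complement symbol.  '#' and '$' are fixed points.
COMPLEMENT = {
    "T": "A", "K": "M", "G": "C", "S": "S", "B": "V", "Y": "R",
    "C": "G", "M": "K", "H": "D", "V": "B", "R": "Y", "D": "H",
    "W": "W", "A": "T", "#": "#", "$": "$",
}

#: gamma(base) -- the IUPAC symbols whose base set contains the given base.
GAMMA = {
    g: frozenset(c for c, bs in BASES_OF_CODE.items() if g in bs)
    for g in "ACGT"
}

CODE_OF_BASESET = {frozenset(bs): c for c, bs in BASES_OF_CODE.items()}

# ---------------------------------------------------------------------------
# integer-coded views

CODE = {c: i for i, c in enumerate(SYMBOL_ORDER)}
NSYM = len(SYMBOL_ORDER)

SENTINEL = CODE["$"]
SEPARATOR = CODE["#"]

_decode = np.frombuffer(SYMBOL_ORDER.encode(), dtype=np.uint8)

_encode_lut = np.full(256, 255, dtype=np.uint8)
for _c, _i in CODE.items():
    _encode_lut[ord(_c)] = _i
    _encode_lut[ord(_c.lower())] = _i

#: complement, as a code -> code lookup table
COMP_CODE = np.array([CODE[COMPLEMENT[c]] for c in SYMBOL_ORDER], dtype=np.uint8)

#: True for codes in sigma_poly
IS_POLY = np.array([c in SIGMA_POLY for c in SYMBOL_ORDER], dtype=bool)

#: gamma sets as sorted code arrays, keyed by read base
GAMMA_CODES = {
    g: np.array(sorted(CODE[c] for c in GAMMA[g]), dtype=np.uint8) for g in "ACGT"
}

#: COMPAT[b, s] -- does text symbol code s satisfy read base b (b indexes "ACGT")
COMPAT = np.zeros((4, NSYM), dtype=bool)
for _bi, _g in enumerate("ACGT"):
    COMPAT[_bi, GAMMA_CODES[_g]] = True

#: read base character -> row of COMPAT (A/C/G/T only)
BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


def encode(s: str) -> np.ndarray:
    """Encode a symbol string to the internal uint8 representation."""
    arr = _encode_lut[np.frombuffer(s.encode(), dtype=np.uint8)]
    if (arr == 255).any():
        bad = s[int(np.argmax(arr == 255))]
        raise ValueError(f"symbol {bad!r} is not in the pangenome alphabet")
    return arr


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _decode[np.asarray(codes, dtype=np.uint8)].tobytes().decode()


@dataclass(frozen=True)
class IUPACTables:
    """Bundled IUPAC lookup tables (code <-> base set, complement, gamma)."""

    code_of_baseset: dict = field(default_factory=lambda: dict(CODE_OF_BASESET))
    baseset_of_code: dict = field(
        default_factory=lambda: {c: frozenset(bs) for c, bs in BASES_OF_CODE.items()}
    )
    complement: dict = field(default_factory=lambda: dict(COMPLEMENT))
    gamma: dict = field(default_factory=lambda: dict(GAMMA))


TABLES = IUPACTables()
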