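"""Small shared helpers: rounding and sequence alphabet utilities."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from Bio.Seq import reverse_complement as _bio_revcomp

#: unambiguous DNA alphabet
DNA_BASES = ("A", "C", "G", "T")

#: IUPAC ambiguity codes (everything legal in a DNA string besides ACGT)
IUPAC_AMBIGUOUS = frozenset("RYSWKMBDHVN")

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables),
    unlike builtin round() which rounds ties to even."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; IUPAC ambiguity codes are
    complemented per their definitions (R<->Y, S<->S, ...)."""
    return str(_bio_revcomp(seq))


def complement_base(base: str) -> str:
    """Watson-Crick complement of a single unambiguous base."""
    return _COMPLEMENT[base]


def is_wc_pair(a: str, b: str) -> bool:
    """True when two bases form a Watson-Crick pair (A:T or G:C)."""
    return _COMPLEMENT.get(a) == b


def normalize_codon(codon: str) -> str:
    """Uppercase and convert RNA spelling to DNA (U -> T)."""
    return codon.upper().replace("U", "T")


def to_rna(codon: str) -> str:
    return codon.upper().replace("T", "U")
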