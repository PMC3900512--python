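"""Codon counting, RSCU and start/stop tabulation under mitochondrial
genetic codes.

Relative synonymous codon usage (RSCU) of codon *c* in synonymous family
*F* is ``n_c * |F| / sum_{c' in F} n_{c'}`` — the observed count divided
by the count expected if all synonyms were used equally; 1.0 means no
bias.  The default genetic code is NCBI translation table 5
(invertebrate mitochondrial: AUA=Met, UGA=Trp, AGA/AGG=Ser — so serine
has an 8-codon family and the stop family is {UAA, UAG}).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from ._util import DNA_BASES, normalize_codon, round_half_up, to_rna
from .errors import EmptyInputError, FrameError
from .model import FeatureClass, MitoGenome

ALL_CODONS = tuple("".join(p) for p in itertools.product(DNA_BASES, repeat=3))

#: amino-acid one-letter code used for termination codons
STOP = "*"


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid map plus its derived synonymous families."""

    table_id: int
    codon_to_aa: Mapping[str, str]
    start_codons: tuple[str, ...]

    @classmethod
    def from_table_id(cls, table_id: int = 5) -> "GeneticCode":
        """Build from an NCBI translation table (via Biopython)."""
        table = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = {c: aa for c, aa in table.forward_table.items()}
        for c in table.stop_codons:
            mapping[c] = STOP
        assert len(mapping) == 64
        return cls(table_id, mapping, tuple(table.start_codons))

    def aa(self, codon: str) -> str:
        return self.codon_to_aa[normalize_codon(codon)]

    @cached_property
    def families(self) -> dict[str, tuple[str, ...]]:
        """Amino acid -> synonymous codon family (stops form their own)."""
        fam: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fam.setdefault(self.codon_to_aa[codon], []).append(codon)
        return {aa: tuple(cs) for aa, cs in fam.items()}

    @cached_property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families[STOP]


#: NCBI transl_table 5, the default for insect mitogenomes
INVERTEBRATE_MITO = GeneticCode.from_table_id(5)


@dataclass
class CodonUsageTable:
    """Per-codon counts over a CDS set, with RSCU derived on demand."""

    counts: dict[str, int]
    code: GeneticCode = INVERTEBRATE_MITO
    ambiguous: int = 0

    def __post_init__(self) -> None:
        full = {c: 0 for c in ALL_CODONS}
        full.update({normalize_codon(c): int(n) for c, n in self.counts.items()})
        unknown = set(full) - set(ALL_CODONS)
        if unknown:
            raise ValueError(f"not DNA codons: {sorted(unknown)}")
        if any(n < 0 for n in full.values()):
            raise ValueError("negative codon count")
        self.counts = full

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def family_total(self, aa: str) -> int:
        return sum(self.counts[c] for c in self.code.families[aa])

    def to_frame(self, alphabet: str = "RNA", decimals: int = 2) -> pd.DataFrame:
        """Table in the conventional 4x16 codon-box order (rows grouped by
        first base then third base, columns scanning the second base)."""
        values = rscu(self)
        # codon-box order: first base U,C,A,G (outer), third base U,C,A,G
        # (inner rows), second base U,C,A,G (columns) -> flattened row-major
        box = "TCAG"
        order = [b1 + b2 + b3 for b1 in box for b3 in box for b2 in box]
        rows = []
        for codon in order:
            v = values[codon]
            rows.append({
                "codon": to_rna(codon) if alphabet.upper() == "RNA" else codon,
                "aa": self.code.codon_to_aa[codon],
                "n": self.counts[codon],
                "rscu": None if v is None else round_half_up(v, decimals),
            })
        return pd.DataFrame(rows)


def count_codons(
    cds_list: Sequence[str], code: GeneticCode = INVERTEBRATE_MITO,
    skip_invalid: bool = False,
) -> CodonUsageTable:
    """Count every codon (initiators and terminators included) of every
    CDS.  Codons containing ambiguity codes go to the ``ambiguous``
    bucket, not to any family."""
    if not cds_list:
        raise EmptyInputError("no coding sequences supplied")
    counts: dict[str, int] = {}
    ambiguous = 0
    for i, cds in enumerate(cds_list):
        cds = normalize_codon(cds)
        if len(cds) % 3:
            if skip_invalid:
                continue
            raise FrameError(f"CDS #{i} length {len(cds)} not divisible by 3")
        for k in range(0, len(cds), 3):
            codon = cds[k:k + 3]
            if codon in code.codon_to_aa:
                counts[codon] = counts.get(codon, 0) + 1
            else:
                ambiguous += 1
    return CodonUsageTable(counts, code, ambiguous)


def rscu(table: CodonUsageTable) -> dict[str, Optional[float]]:
    """RSCU for every codon; codons of a family with zero total count map
    to None (undefined, reported missing rather than zero)."""
    out: dict[str, Optional[float]] = {}
    for aa, family in table.code.families.items():
        total = sum(table.counts[c] for c in family)
        for c in family:
            out[c] = table.counts[c] * len(family) / total if total else None
    return out


def amino_acid_usage(
    table: CodonUsageTable, include_stops: bool = False
) -> dict[str, float]:
    """Percentage of counted codons per amino acid (stops excluded from
    the denominator unless requested)."""
    totals = {
        aa: table.family_total(aa)
        for aa in table.code.families
        if include_stops or aa != STOP
    }
    denom = sum(totals.values())
    if denom == 0:
        raise EmptyInputError("codon usage table is empty")
    return {aa: 100.0 * n / denom for aa, n in totals.items()}


def start_stop_table(
    genome: MitoGenome, code: GeneticCode = INVERTEBRATE_MITO
) -> pd.DataFrame:
    """First and last in-frame codons of every annotated protein-coding
    gene (coding sense), with classification: is the initiator one of the
    code's permitted start codons, and is the terminator a complete stop
    codon.  Spans not divisible by three are reported as truncated."""
    rows = []
    for f in genome.annotation.by_class(FeatureClass.PCG):
        cds = genome.feature_sequence(f)
        start = cds[:3]
        remainder = len(cds) % 3
        stop = cds[-3:] if remainder == 0 else cds[-remainder:]
        rows.append({
            "gene": f.name,
            "start_codon": start,
            "stop_codon": stop,
            "start_canonical": start in code.start_codons,
            "stop_status": (
                "truncated" if remainder
                else "complete" if stop in code.stop_codons
                else "noncanonical"
            ),
        })
    return pd.DataFrame(rows)
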