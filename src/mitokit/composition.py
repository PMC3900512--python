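"""Nucleotide composition, AT/GC content and strand-skew statistics.

AT-skew = (A - T) / (A + T) and GC-skew = (G - C) / (G + C) measure the
asymmetry of base usage between the two strands of a mitogenome; both lie
in [-1, 1] and are antisymmetric under reverse complement.  Profiles can
be computed for whole genomes, pooled feature classes, and the three
codon positions of the protein-coding genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from ._util import DNA_BASES, IUPAC_AMBIGUOUS, round_half_up
from .errors import EmptyInputError, FrameError
from .model import FeatureClass, MitoGenome


@dataclass
class CompositionProfile:
    """Base counts and the statistics derived from them for one region.

    Ambiguity codes (IUPAC) are counted in ``ambiguous`` and excluded
    from every denominator.  Skews are ``None`` when their denominator
    is zero (undefined, not zero).
    """

    counts: dict[str, int]
    ambiguous: int = 0
    label: str = ""

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def proportion(self, base: str) -> float:
        return 100.0 * self.counts[base] / self.n

    @property
    def proportions(self) -> dict[str, float]:
        return {b: self.proportion(b) for b in DNA_BASES}

    @property
    def at_content(self) -> float:
        return self.proportion("A") + self.proportion("T")

    @property
    def gc_content(self) -> float:
        return self.proportion("G") + self.proportion("C")

    @property
    def at_skew(self) -> Optional[float]:
        a, t = self.counts["A"], self.counts["T"]
        return (a - t) / (a + t) if a + t else None

    @property
    def gc_skew(self) -> Optional[float]:
        g, c = self.counts["G"], self.counts["C"]
        return (g - c) / (g + c) if g + c else None

    def rounded_row(self, pct_decimals: int = 1, skew_decimals: int = 2) -> dict:
        """One report row at printed precision (half-up rounding)."""
        row = {b: round_half_up(self.proportion(b), pct_decimals) for b in "ATGC"}
        row["A+T"] = round_half_up(self.at_content, pct_decimals)
        row["G+C"] = round_half_up(self.gc_content, pct_decimals)
        for key, value in (("AT-skew", self.at_skew), ("GC-skew", self.gc_skew)):
            row[key] = None if value is None else round_half_up(value, skew_decimals)
        return row


def merge_profiles(profiles: Iterable[CompositionProfile], label: str = "") -> CompositionProfile:
    """Count-weighted pool of several profiles (== profile of the
    concatenation of their regions)."""
    counts = {b: 0 for b in DNA_BASES}
    ambiguous = 0
    for p in profiles:
        for b in DNA_BASES:
            counts[b] += p.counts[b]
        ambiguous += p.ambiguous
    return CompositionProfile(counts, ambiguous, label)


def base_composition(seq: str, label: str = "") -> CompositionProfile:
    """Composition profile of one sequence.

    Raises :class:`EmptyInputError` on an empty sequence and ValueError
    on characters that are neither bases nor IUPAC ambiguity codes.
    """
    if not seq:
        raise EmptyInputError("empty sequence")
    seq = seq.upper()
    counts = {b: seq.count(b) for b in DNA_BASES}
    ambiguous = len(seq) - sum(counts.values())
    if ambiguous:
        bad = set(seq) - set(DNA_BASES) - IUPAC_AMBIGUOUS
        if bad:
            raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return CompositionProfile(counts, ambiguous, label)


def skew_from_proportions(
    a: float, t: float, g: float, c: float, decimals: Optional[int] = 2
) -> tuple[Optional[float], Optional[float]]:
    """(AT-skew, GC-skew) from base percentages (or any proportional
    measure); a zero denominator yields None for that skew."""
    at = (a - t) / (a + t) if a + t else None
    gc = (g - c) / (g + c) if g + c else None
    if decimals is not None:
        at = None if at is None else round_half_up(at, decimals)
        gc = None if gc is None else round_half_up(gc, decimals)
    return at, gc


def codon_position_composition(
    cds_list: Sequence[str], skip_invalid: bool = False
) -> tuple[CompositionProfile, CompositionProfile, CompositionProfile]:
    """Pool codon positions 1, 2 and 3 across a set of coding sequences
    (each already in reading orientation) into three profiles.

    A CDS whose length is not divisible by three raises
    :class:`FrameError`, or is skipped with a warning when
    ``skip_invalid`` is set.
    """
    if not cds_list:
        raise EmptyInputError("no coding sequences supplied")
    parts: list[list[str]] = [[], [], []]
    for i, cds in enumerate(cds_list):
        if len(cds) % 3:
            if skip_invalid:
                warnings.warn(f"CDS #{i} length {len(cds)} not divisible by 3; skipped")
                continue
            raise FrameError(f"CDS #{i} length {len(cds)} not divisible by 3")
        for pos in range(3):
            parts[pos].append(cds[pos::3])
    return tuple(
        base_composition("".join(parts[pos]), label=f"codon position {pos + 1}")
        for pos in range(3)
    )  # type: ignore[return-value]


#: row order of the standard per-region report
REPORT_ROWS = (
    "Whole mtDNA", "Protein coding genes", "1st codon position",
    "2nd codon position", "3rd codon position", "tRNA genes",
    "lrRNA", "srRNA", "A+T-rich region",
)


def region_composition_report(
    genome: MitoGenome, pct_decimals: int = 1, skew_decimals: int = 2
) -> pd.DataFrame:
    """Composition/skew table for the standard mitogenome regions:
    whole genome, pooled PCGs, the three codon positions, pooled tRNAs,
    each rRNA, and the A+T-rich (control) region.

    Protein-coding genes contribute their coding-sense (mRNA-like)
    sequence — N-strand genes are reverse-complemented — so the codon
    position rows are computed in reading frame.  Missing feature
    classes drop their row; the reasons are listed in
    ``DataFrame.attrs["findings"]``.
    """
    ann = genome.annotation
    profiles: dict[str, CompositionProfile] = {}
    findings: list[str] = []

    profiles["Whole mtDNA"] = base_composition(genome.sequence, "Whole mtDNA")

    pcgs = ann.by_class(FeatureClass.PCG)
    if pcgs:
        cds = [genome.feature_sequence(f) for f in pcgs]
        profiles["Protein coding genes"] = merge_profiles(
            (base_composition(s) for s in cds), "Protein coding genes")
        p1, p2, p3 = codon_position_composition(cds, skip_invalid=True)
        profiles["1st codon position"] = p1
        profiles["2nd codon position"] = p2
        profiles["3rd codon position"] = p3
    else:
        findings.append("no protein-coding genes annotated; PCG rows omitted")

    trnas = ann.by_class(FeatureClass.TRNA)
    if trnas:
        profiles["tRNA genes"] = merge_profiles(
            (base_composition(genome.feature_sequence(f)) for f in trnas),
            "tRNA genes")
    else:
        findings.append("no tRNA genes annotated; tRNA row omitted")

    for label in ("lrRNA", "srRNA"):
        hits = [f for f in ann.by_class(FeatureClass.RRNA) if f.name.lower().startswith(label.lower())]
        if hits:
            profiles[label] = base_composition(genome.feature_sequence(hits[0]), label)
        else:
            findings.append(f"no {label} feature annotated; row omitted")

    crs = ann.by_class(FeatureClass.CONTROL_REGION)
    if crs:
        profiles["A+T-rich region"] = base_composition(
            genome.feature_sequence(crs[0]), "A+T-rich region")
    else:
        findings.append("no control region annotated; A+T-rich row omitted")

    rows = {
        label: profiles[label].rounded_row(pct_decimals, skew_decimals)
        for label in REPORT_ROWS
        if label in profiles
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "Region"
    df.attrs["findings"] = findings
    df.attrs["profiles"] = profiles
    return df
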