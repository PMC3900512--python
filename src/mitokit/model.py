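"""Core data model for circular annotated mitochondrial genomes.

Coordinates follow the convention of published mitogenome annotation
tables: 1-based, inclusive on both ends, given on the reference (J,
majority) strand.  A feature with ``end < start`` wraps across the
origin of a circular genome.  Strand is ``"J"`` (majority / H) or
``"N"`` (minority / L); N-strand features are read as the reverse
complement of the reference strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Optional

from ._util import reverse_complement
from .errors import CoordinateError, OrderingError, StateError


class FeatureClass(str, Enum):
    """Functional class of an annotated mitogenome feature."""

    PCG = "PCG"
    TRNA = "tRNA"
    RRNA = "rRNA"
    CONTROL_REGION = "control_region"


#: expected census of a complete insect mitogenome annotation
#: (13 protein-coding genes, 22 tRNAs, 2 rRNAs, 1 control region)
COMPLETE_CENSUS = {
    FeatureClass.PCG: 13,
    FeatureClass.TRNA: 22,
    FeatureClass.RRNA: 2,
    FeatureClass.CONTROL_REGION: 1,
}

#: canonical reading order of the 13 protein-coding genes used when
#: concatenating genes across genomes
PCG_ORDER = (
    "ND2", "COI", "COII", "ATP8", "ATP6", "COIII", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature (gene, tRNA, rRNA or control region).

    ``declared_length`` optionally carries a published length that may
    disagree with the coordinate span; :func:`validate_annotation`
    reports such disagreements rather than silently correcting either
    value.
    """

    name: str
    feature_class: FeatureClass
    start: int
    end: int
    strand: str = "J"
    anticodon: Optional[str] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    declared_length: Optional[int] = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise ValueError(f"strand must be 'J' or 'N', got {self.strand!r}")
        object.__setattr__(self, "feature_class", FeatureClass(self.feature_class))

    @property
    def wraps(self) -> bool:
        """True for a feature crossing the origin (end < start)."""
        return self.end < self.start


@dataclass
class AnnotationTable:
    """Ordered annotation of one mitogenome (ascending start position)."""

    features: list[GeneFeature]
    genome_length: int
    circular: bool = True

    def __iter__(self) -> Iterator[GeneFeature]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def by_class(self, feature_class: FeatureClass) -> list[GeneFeature]:
        feature_class = FeatureClass(feature_class)
        return [f for f in self.features if f.feature_class is feature_class]

    def rotated(self, offset: int) -> "AnnotationTable":
        """Annotation as it would read after re-linearizing the circular
        genome so that old position ``offset + 1`` becomes position 1."""
        if not self.circular:
            raise StateError("rotation requires a circular genome")
        G = self.genome_length
        offset %= G

        def shift(p: int) -> int:
            return (p - 1 - offset) % G + 1

        moved = [replace(f, start=shift(f.start), end=shift(f.end)) for f in self.features]
        moved.sort(key=lambda f: f.start)
        return AnnotationTable(moved, G, True)


@dataclass
class MitoGenome:
    """A (possibly sequence-less) annotated mitochondrial genome."""

    annotation: AnnotationTable
    sequence: Optional[str] = None
    identifier: str = ""

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.annotation.genome_length:
                raise ValueError(
                    f"sequence length {len(self.sequence)} != annotated "
                    f"genome length {self.annotation.genome_length}"
                )

    def feature_sequence(self, feature: GeneFeature | str) -> str:
        if isinstance(feature, str):
            feature = self.annotation.get(feature)
        return extract_feature_sequence(self, feature)


@dataclass(frozen=True)
class Finding:
    """A validation observation (never an exception)."""

    category: str
    feature: Optional[str]
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = f"[{self.feature}] " if self.feature else ""
        return f"{self.category}: {where}{self.message}"


def feature_length(
    feature: GeneFeature,
    genome_length: Optional[int] = None,
    circular: bool = False,
) -> int:
    """Length in nucleotides of a feature, handling origin-spanning
    features on circular genomes (where end < start)."""
    if genome_length is not None:
        if not (1 <= feature.start <= genome_length and 1 <= feature.end <= genome_length):
            raise CoordinateError(
                f"{feature.name}: coordinates ({feature.start}, {feature.end}) "
                f"outside [1, {genome_length}]"
            )
    elif feature.start < 1 or feature.end < 1:
        raise CoordinateError(f"{feature.name}: coordinates must be >= 1")
    if not feature.wraps:
        return feature.end - feature.start + 1
    if genome_length is None or not circular:
        raise CoordinateError(
            f"{feature.name}: end < start is only legal on a circular genome"
        )
    return genome_length - feature.start + 1 + feature.end


def intergenic_table(annotation: AnnotationTable) -> list[tuple[str, Optional[int]]]:
    """Intergenic nucleotides (IGN) preceding each feature in table order.

    ``ign_i = start_i - end_{i-1} - 1``; negative values are gene
    overlaps.  The first feature's entry is the wrap boundary
    ``start_0 + genome_length - end_last - 1`` on circular genomes and
    ``None`` on linear ones.
    """
    feats = annotation.features
    if any(feats[i].start > feats[i + 1].start for i in range(len(feats) - 1)):
        raise OrderingError("features must be sorted by ascending start")
    out: list[tuple[str, Optional[int]]] = []
    for i, f in enumerate(feats):
        if i == 0:
            if annotation.circular and feats:
                ign: Optional[int] = f.start + annotation.genome_length - feats[-1].end - 1
            else:
                ign = None
        else:
            ign = f.start - feats[i - 1].end - 1
        out.append((f.name, ign))
    return out


def extract_feature_sequence(genome: MitoGenome, feature: GeneFeature) -> str:
    """Feature sequence in reading orientation: the [start, end] slice of
    the reference strand, reverse-complemented for N-strand features."""
    if genome.sequence is None:
        raise StateError("genome has no sequence")
    seq = genome.sequence
    if feature.wraps:
        if not genome.annotation.circular:
            raise CoordinateError(f"{feature.name}: wrapping feature on linear genome")
        sub = seq[feature.start - 1:] + seq[: feature.end]
    else:
        sub = seq[feature.start - 1: feature.end]
    return reverse_complement(sub) if feature.strand == "N" else sub


def gene_order_signature(annotation: AnnotationTable) -> str:
    """Canonical gene-order string: feature names in order with N-strand
    genes prefixed ``-``, rotation-normalized so two genomes compare
    equal iff their gene order and strands match regardless of where the
    circle was linearized.  Rotation starts at tRNA-Ile when present,
    otherwise at the lexicographically smallest rotation.
    """
    tokens = tuple(
        (f.name if f.strand == "J" else f"-{f.name}") for f in annotation.features
    )
    if not tokens:
        return ""
    names = [f.name for f in annotation.features]
    if "tRNA-Ile" in names:
        k = names.index("tRNA-Ile")
        tokens = tokens[k:] + tokens[:k]
    else:
        rotations = [tokens[i:] + tokens[:i] for i in range(len(tokens))]
        tokens = min(rotations)
    return " ".join(tokens)


def validate_annotation(annotation: AnnotationTable) -> list[Finding]:
    """Sanity report for an annotation table.  An empty list means clean.

    Reported findings: coordinates outside [1, genome_length]; wrapping
    features on a linear genome; out-of-order rows; declared lengths that
    disagree with the coordinate span; PCG spans not divisible by three
    (possible truncated stop codon); and, for near-complete tables, class
    counts departing from the canonical 13 PCG / 22 tRNA / 2 rRNA /
    1 control-region census.
    """
    findings: list[Finding] = []
    G = annotation.genome_length
    for f in annotation.features:
        if not (1 <= f.start <= G and 1 <= f.end <= G):
            findings.append(Finding(
                "coordinate", f.name,
                f"coordinates ({f.start}, {f.end}) outside [1, {G}]"))
            continue
        if f.wraps and not annotation.circular:
            findings.append(Finding(
                "coordinate", f.name,
                "end < start is not legal on a linear genome"))
            continue
        span = feature_length(f, G, annotation.circular)
        if f.declared_length is not None and f.declared_length != span:
            findings.append(Finding(
                "length_mismatch", f.name,
                f"declared length {f.declared_length} != coordinate span {span}"))
        if f.feature_class is FeatureClass.PCG and span % 3:
            findings.append(Finding(
                "frame", f.name,
                f"span {span} not divisible by 3 "
                f"(possible truncated/incomplete stop codon)"))
    starts = [f.start for f in annotation.features]
    if starts != sorted(starts):
        findings.append(Finding("ordering", None, "features not sorted by start"))
    if len(annotation.features) >= 30:
        for cls, expected in COMPLETE_CENSUS.items():
            n = len(annotation.by_class(cls))
            if n != expected:
                findings.append(Finding(
                    "census", None,
                    f"{n} {cls.value} features (expected {expected} in a "
                    f"complete insect mitogenome)"))
    return findings


def telescoping_sum(annotation: AnnotationTable) -> int:
    """Sum of all feature lengths plus all boundary IGNs (including the
    wrap boundary).  Equals genome_length on any circular annotation —
    the conservation identity used to cross-check published tables."""
    total = sum(
        feature_length(f, annotation.genome_length, annotation.circular)
        for f in annotation.features
    )
    total += sum(ign for _, ign in intergenic_table(annotation) if ign is not None)
    return total
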