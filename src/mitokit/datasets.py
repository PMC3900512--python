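"""Packaged reference tables for the mitogenome of the stonefly
*Kamimuria wangi* (GenBank KC894944, 16,179 bp).

Three small TSVs ship with the package, transcribed verbatim from the
published annotation of that genome:

* ``kamimuria_wangi_annotation.tsv`` — the 38-feature annotation
  (coordinates, strand, published lengths, start/stop codons, published
  intergenic nucleotide counts).  Two published cells for COII (length
  686, IGN 56) disagree with the row's own coordinates (span 696,
  IGN 5); the file keeps the published values and
  :func:`mitokit.model.validate_annotation` flags the discrepancy.
* ``kamimuria_wangi_codon_usage.tsv`` — codon counts and published RSCU
  of the 13 protein-coding genes.
* ``kamimuria_wangi_composition.tsv`` — per-region base proportions and
  published AT/GC-skews for *K. wangi* (Kw) and the confamilial
  comparator *Pteronarcys princeps* (Pp).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .codon import INVERTEBRATE_MITO, CodonUsageTable
from ._util import normalize_codon
from .model import AnnotationTable, FeatureClass, GeneFeature

GENOME_LENGTH = 16179
ACCESSION = "KC894944"


def _data_path(name: str):
    return resources.files("mitokit.data").joinpath(name)


def load_annotation_frame() -> pd.DataFrame:
    """The annotation TSV as printed (including the two discrepant COII
    cells), with pandas NA for blank cells."""
    with resources.as_file(_data_path("kamimuria_wangi_annotation.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"start": int, "end": int})


def load_annotation() -> AnnotationTable:
    """The K. wangi annotation as an :class:`AnnotationTable`.

    ``declared_length`` carries the published length column so that
    validation can surface published-vs-coordinate disagreements.
    """
    df = load_annotation_frame()
    feats = [
        GeneFeature(
            name=row["name"],
            feature_class=FeatureClass(row["feature_class"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row["strand"],
            declared_length=(None if pd.isna(row["length"]) else int(row["length"])),
            start_codon=(None if pd.isna(row["start_codon"]) else row["start_codon"]),
            stop_codon=(None if pd.isna(row["stop_codon"]) else row["stop_codon"]),
        )
        for _, row in df.iterrows()
    ]
    return AnnotationTable(feats, GENOME_LENGTH, circular=True)


def load_codon_usage_frame() -> pd.DataFrame:
    """Published codon counts and RSCU (RNA alphabet)."""
    with resources.as_file(_data_path("kamimuria_wangi_codon_usage.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_codon_counts() -> CodonUsageTable:
    """Published codon counts as a :class:`CodonUsageTable` under the
    invertebrate mitochondrial code."""
    df = load_codon_usage_frame()
    counts = {normalize_codon(c): int(n) for c, n in zip(df["codon"], df["count"])}
    return CodonUsageTable(counts, INVERTEBRATE_MITO)


def load_composition_frame() -> pd.DataFrame:
    """Published per-region proportions and skews for Kw and Pp."""
    with resources.as_file(_data_path("kamimuria_wangi_composition.tsv")) as p:
        return pd.read_csv(p, sep="\t")
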