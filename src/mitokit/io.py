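"""Readers and writers for the formats mitogenome annotations travel in.

GenBank flat files and FASTA go through Biopython; the plain TSV
annotation dialect mirrors the columns of published annotation tables
(name, class, 1-based inclusive start/end, strand, length, start/stop
codon).  Coordinate conversion between GenBank's 0-based half-open
locations and the package's 1-based inclusive convention happens here
and only here.
"""

from __future__ import annotations

import os
from typing import Iterable, Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import AnnotationTable, FeatureClass, GeneFeature, MitoGenome

PathLike = Union[str, os.PathLike]

_CLASS_TO_GENBANK = {
    FeatureClass.PCG: "CDS",
    FeatureClass.TRNA: "tRNA",
    FeatureClass.RRNA: "rRNA",
    FeatureClass.CONTROL_REGION: "D-loop",
}
_GENBANK_TO_CLASS = {
    "CDS": FeatureClass.PCG,
    "tRNA": FeatureClass.TRNA,
    "rRNA": FeatureClass.RRNA,
    "D-loop": FeatureClass.CONTROL_REGION,
    "misc_feature": FeatureClass.CONTROL_REGION,
}

TSV_COLUMNS = ["name", "feature_class", "start", "end", "strand",
               "length", "start_codon", "stop_codon"]


def read_genbank(path: PathLike) -> MitoGenome:
    """One annotated genome from a GenBank flat file.

    CDS features map to PCG, tRNA/rRNA to their classes, and
    D-loop/misc_feature to the control region; a ``transl_table``
    qualifier, when present, is kept in the feature notes.  Features with
    compound (origin-spanning) locations are not supported.
    """
    record = SeqIO.read(str(path), "genbank")
    feats: list[GeneFeature] = []
    for sf in record.features:
        if sf.type not in _GENBANK_TO_CLASS:
            continue
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("product")
                or sf.qualifiers.get("note") or [sf.type])[0]
        notes = ""
        if "transl_table" in sf.qualifiers:
            notes = f"transl_table={sf.qualifiers['transl_table'][0]}"
        feats.append(GeneFeature(
            name=name,
            feature_class=_GENBANK_TO_CLASS[sf.type],
            start=int(sf.location.start) + 1,
            end=int(sf.location.end),
            strand="N" if sf.location.strand == -1 else "J",
            notes=notes,
        ))
    feats.sort(key=lambda f: f.start)
    circular = record.annotations.get("topology", "circular") == "circular"
    ann = AnnotationTable(feats, len(record.seq), circular=circular)
    return MitoGenome(annotation=ann, sequence=str(record.seq),
                      identifier=record.id)


def write_genbank(genome: MitoGenome, path: PathLike,
                  transl_table: int = 5) -> None:
    """Write a genome (with sequence) as a GenBank flat file."""
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier or "synthetic",
        name=(genome.identifier or "synthetic")[:16].replace("-", "_"),
        description="mitochondrial genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.annotation.circular else "linear",
        },
    )
    for f in genome.annotation.features:
        qualifiers = {"gene": [f.name]}
        if f.feature_class is FeatureClass.PCG:
            qualifiers["transl_table"] = [str(transl_table)]
        location = FeatureLocation(f.start - 1, f.end,
                                   strand=-1 if f.strand == "N" else 1)
        record.features.append(SeqFeature(
            location, type=_CLASS_TO_GENBANK[f.feature_class],
            qualifiers=qualifiers))
    SeqIO.write([record], str(path), "genbank")


def annotation_to_frame(annotation: AnnotationTable) -> pd.DataFrame:
    rows = [{
        "name": f.name,
        "feature_class": f.feature_class.value,
        "start": f.start,
        "end": f.end,
        "strand": f.strand,
        "length": f.declared_length,
        "start_codon": f.start_codon,
        "stop_codon": f.stop_codon,
    } for f in annotation.features]
    return pd.DataFrame(rows, columns=TSV_COLUMNS)


def write_annotation_tsv(annotation: AnnotationTable, path: PathLike) -> None:
    annotation_to_frame(annotation).to_csv(path, sep="\t", index=False)


def read_annotation_tsv(path: PathLike, genome_length: int,
                        circular: bool = True) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t")
    feats = [
        GeneFeature(
            name=row["name"],
            feature_class=FeatureClass(row["feature_class"]),
            start=int(row["start"]),
            end=int(row["end"]),
            strand=row.get("strand", "J") if pd.notna(row.get("strand")) else "J",
            declared_length=(int(row["length"])
                             if "length" in row and pd.notna(row["length"]) else None),
            start_codon=(row["start_codon"]
                         if "start_codon" in row and pd.notna(row["start_codon"]) else None),
            stop_codon=(row["stop_codon"]
                        if "stop_codon" in row and pd.notna(row["stop_codon"]) else None),
        )
        for _, row in df.iterrows()
    ]
    return AnnotationTable(feats, genome_length, circular=circular)


def read_fasta(path: PathLike) -> dict[str, str]:
    """All records of a FASTA file as {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
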