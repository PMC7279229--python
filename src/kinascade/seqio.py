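"""Sequence and annotation I/O: FASTA proteomes, GFF3 gene models, reports.

Conventions shared by the whole package:

* protein coordinates are 0-based half-open internally;
* GFF3 coordinates are kept 1-based inclusive at the file boundary and
  converted exactly (the conversion is involutive);
* one protein per gene — when a gene has several mRNAs the primary transcript
  is the one with the longest CDS (ties go to the first listed), matching the
  "primary transcripts" convention of plant genome portals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .motifs import AA20

VALID_RESIDUES = AA20 | {"X"}


class SeqIOError(ValueError):
    pass


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its identifier and source gene."""

    id: str
    gene_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise SeqIOError(f"record {self.id!r}: empty sequence")
        for i, c in enumerate(self.sequence):
            if c not in VALID_RESIDUES:
                raise SeqIOError(
                    f"record {self.id!r}: illegal residue {c!r} at position {i + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """A gene with its chromosome, strand, span and primary-transcript exons.

    Coordinates are 1-based inclusive nucleotides, as in GFF3.
    """

    gene_id: str
    chromosome: str
    strand: str
    gene_start: int
    gene_end: int
    exons: tuple[tuple[int, int], ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.strand not in "+-":
            raise SeqIOError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if self.gene_end < self.gene_start:
            raise SeqIOError(f"gene {self.gene_id!r}: reversed coordinates")
        prev_end = None
        for s, e in self.exons:
            if e < s:
                raise SeqIOError(f"gene {self.gene_id!r}: reversed exon {s}..{e}")
            if prev_end is not None and s <= prev_end:
                raise SeqIOError(f"gene {self.gene_id!r}: exons overlap or are unsorted")
            prev_end = e
        if self.exons:
            if min(s for s, _ in self.exons) < self.gene_start or max(
                e for _, e in self.exons
            ) > self.gene_end:
                raise SeqIOError(f"gene {self.gene_id!r}: exons outside gene span")

    @property
    def length_nt(self) -> int:
        return self.gene_end - self.gene_start + 1


def to_internal(start_1based: int, end_1based: int) -> tuple[int, int]:
    """GFF3 1-based inclusive -> 0-based half-open."""
    return start_1based - 1, end_1based


def to_gff3(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open -> GFF3 1-based inclusive."""
    return start0 + 1, end0


def read_fasta(path) -> list[ProteinRecord]:
    """Read a protein FASTA; lowercase is up-cased, order is preserved.

    The gene id is taken from a ``gene_id=...`` token in the description when
    present, else the record id itself.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene_id = rec.id
        for token in rec.description.split():
            if token.startswith("gene_id="):
                gene_id = token[len("gene_id=") :]
        records.append(ProteinRecord(rec.id, gene_id, str(rec.seq).upper()))
    if not records:
        raise SeqIOError(f"{path}: no records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise SeqIOError(f"{path}: duplicate record id {dup!r}")
    return records


def write_fasta(records, path) -> Path:
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=f"gene_id={r.gene_id}")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")
    return path


def _cds_length(db, mrna) -> int:
    cds = sum(f.end - f.start + 1 for f in db.children(mrna, featuretype="CDS"))
    if cds:
        return cds
    return sum(f.end - f.start + 1 for f in db.children(mrna, featuretype="exon"))


def read_gff3(path) -> list[GeneModel]:
    """Read gene/mRNA/exon features into one :class:`GeneModel` per gene.

    The primary transcript is the mRNA with the longest CDS (exon total as a
    fallback when no CDS features exist); ties go to the first listed.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    # orphan exon check: every exon's Parent must resolve to a known feature
    known = {f.id for f in db.all_features()}
    for exon in db.features_of_type("exon"):
        for parent_id in exon.attributes.get("Parent", []):
            if parent_id not in known:
                raise SeqIOError(f"exon at {exon.seqid}:{exon.start} has unresolvable "
                                 f"parent {parent_id!r}")

    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if mrnas:
            primary = max(mrnas, key=lambda m: _cds_length(db, m))
            # max() keeps the first maximum, i.e. the tie rule
            exon_feats = list(db.children(primary, featuretype="exon", order_by="start"))
        else:
            exon_feats = list(db.children(gene, featuretype="exon", order_by="start"))
        exons = tuple((f.start, f.end) for f in exon_feats)
        models.append(
            GeneModel(
                gene_id=gene.id,
                chromosome=gene.seqid,
                strand=gene.strand if gene.strand in "+-" else "+",
                gene_start=gene.start,
                gene_end=gene.end,
                exons=exons,
            )
        )
    return models


#: Canonical inventory report columns, in output order.
REPORT_COLUMNS = [
    "id",
    "family",
    "group",
    "txy_variant",
    "loops_found",
    "length_aa",
    "mass_kda",
    "pi",
    "chromosome",
    "exon_count",
    "gene_length_nt",
]


def write_report(rows, path, format: str = "tsv") -> Path:
    """Write inventory rows (list of dicts or DataFrame) as TSV or JSON.

    Round-trip stable: reading the file back yields the same values.
    """
    path = Path(path)
    df = rows.copy() if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    if df.empty:
        df = pd.DataFrame(columns=REPORT_COLUMNS)
    else:
        ordered = [c for c in REPORT_COLUMNS if c in df.columns]
        extra = [c for c in df.columns if c not in ordered]
        df = df[ordered + extra]
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def read_report(path, format: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "tsv"
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    return pd.DataFrame(json.loads(path.read_text()))
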