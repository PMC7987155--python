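"""Readers and writers for every external format the pipeline touches.

Coordinate conventions
----------------------
All internal coordinates are **0-based half-open** intervals ``[start, end)``
on the forward strand of a contig.  GFF3 input/output uses the format's native
1-based inclusive convention; conversion happens at the boundary and nowhere
else.  For a minus-strand gene the *translational start* is the end-most base
of its annotated interval (GFF stores intervals in forward-strand
coordinates).

TSV schemas
-----------
``expression``: gene_id, log2fc, pvalue
``ipd``:        contig, position, strand, ipd_ratio, qv
``orthologs``:  group_id, species_id, gene_id
``sites``:      site [, collection]
Peaks are read from BED4 (chrom, start, end, enrichment).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GeneAnnotation",
    "ExpressionRecord",
    "PeakRecord",
    "IpdRecord",
    "ParseError",
    "SchemaError",
    "read_genome_fasta",
    "read_gene_annotation",
    "read_table",
    "write_table",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_sites",
]

_VALID_BASES = set("ACGTN")


class ParseError(ValueError):
    """Raised when an input file violates its format."""


class SchemaError(ValueError):
    """Raised when a table is missing required columns or fails typing."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """A single contig: uppercase DNA over the alphabet {A, C, G, T, N}."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self):
        bad = set(self.seq) - _VALID_BASES
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains invalid characters: {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene interval in internal 0-based half-open coordinates.

    ``start``/``end`` delimit the annotated gene body on the forward strand.
    The translational start sits at ``start`` for ``+`` genes and at
    ``end`` (exclusive bound, i.e. base ``end - 1``) for ``-`` genes.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    operon_id: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ParseError(f"gene {self.gene_id!r}: strand must be + or -, got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ParseError(f"gene {self.gene_id!r}: require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def translational_start(self) -> int:
        """Forward-strand coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    log2fc: float
    pvalue: float

    def __post_init__(self):
        if not math.isfinite(self.log2fc):
            raise SchemaError(f"gene {self.gene_id!r}: log2fc must be finite")
        if not (0.0 <= self.pvalue <= 1.0):
            raise SchemaError(f"gene {self.gene_id!r}: pvalue {self.pvalue} outside [0, 1]")


@dataclass(frozen=True)
class PeakRecord:
    contig: str
    start: int
    end: int
    enrichment: float

    def __post_init__(self):
        if self.start >= self.end:
            raise SchemaError(f"peak [{self.start}, {self.end}): start must be < end")
        if self.enrichment < 0:
            raise SchemaError("peak enrichment must be nonnegative")


@dataclass(frozen=True)
class IpdRecord:
    contig: str
    position: int
    strand: str
    ipd_ratio: float
    qv: float

    def __post_init__(self):
        if self.ipd_ratio <= 0:
            raise SchemaError(f"ipd_ratio must be positive, got {self.ipd_ratio}")
        if self.qv < 0:
            raise SchemaError("qv must be nonnegative")
        if self.strand not in ("+", "-"):
            raise SchemaError(f"strand must be + or -, got {self.strand!r}")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA into :class:`GenomeSequence` records.

    Sequences are uppercased; ``U`` and any other non-ACGTN character are
    rejected with a :class:`ParseError` naming the offending record.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if "U" in seq:
            raise ParseError(f"record {rec.id!r}: RNA alphabet (U) not accepted")
        records.append(GenomeSequence(id=rec.id, seq=seq))
    return records


def write_genome_fasta(records: Iterable[GenomeSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Gene annotation (GFF3 / TSV)
# ---------------------------------------------------------------------------

def _parse_gff3_attributes(text: str) -> dict:
    out = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gene_annotation(
    path: str | Path,
    dialect: str = "gff3",
    feature_type: str = "gene",
) -> list[GeneAnnotation]:
    """Read gene annotations, converting to 0-based half-open coordinates.

    ``gff3``: native 1-based inclusive columns; only rows whose type column
    equals ``feature_type`` are kept; gene id taken from the ``ID`` or
    ``locus_tag`` attribute.  ``tsv``: explicit internal-coordinate columns
    gene_id, contig, start, end, strand [, operon_id] — round-trips unchanged.
    """
    if dialect == "tsv":
        df = _read_tsv(path, required=["gene_id", "contig", "start", "end", "strand"])
        genes = []
        for i, row in df.iterrows():
            operon = row.get("operon_id")
            if operon is not None and (pd.isna(operon) or operon == ""):
                operon = None
            genes.append(
                GeneAnnotation(
                    gene_id=str(row["gene_id"]),
                    contig=str(row["contig"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=str(row["strand"]),
                    operon_id=None if operon is None else str(operon),
                )
            )
        return genes
    if dialect != "gff3":
        raise ValueError(f"unknown dialect {dialect!r}")

    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated fields, got {len(fields)}")
            contig, _source, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != feature_type:
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if end1 < start1:
                raise ParseError(f"{path}:{lineno}: end < start")
            if strand not in ("+", "-"):
                raise ParseError(f"{path}:{lineno}: unknown strand {strand!r}")
            attrs = _parse_gff3_attributes(attrs_s)
            gene_id = attrs.get("ID") or attrs.get("locus_tag")
            if not gene_id:
                raise ParseError(f"{path}:{lineno}: feature has no ID/locus_tag attribute")
            extra = {k: v for k, v in attrs.items() if k not in ("ID", "locus_tag")}
            # GFF3 1-based inclusive [start1, end1] -> internal 0-based half-open
            genes.append(
                GeneAnnotation(
                    gene_id=gene_id,
                    contig=contig,
                    start=start1 - 1,
                    end=end1,
                    strand=strand,
                    extra=extra,
                )
            )
    return genes


def write_gene_annotation_gff3(genes: Iterable[GeneAnnotation], path: str | Path,
                               feature_type: str = "gene") -> None:
    """Inverse of :func:`read_gene_annotation` (gff3 dialect)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            for k, v in g.extra.items():
                attrs += f";{k}={v}"
            fh.write(
                f"{g.contig}\t.\t{feature_type}\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# Typed tables
# ---------------------------------------------------------------------------

_SCHEMAS = {
    "expression": ["gene_id", "log2fc", "pvalue"],
    "ipd": ["contig", "position", "strand", "ipd_ratio", "qv"],
    "orthologs": ["group_id", "species_id", "gene_id"],
    "sites": ["site"],
}


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_table(path: str | Path, schema: str):
    """Read a TSV of the named schema into typed records.

    Returns a list of dataclass records (``expression`` / ``ipd``) or a
    :class:`pandas.DataFrame` (``orthologs`` / ``sites``), raising
    :class:`SchemaError` with the 1-based data row number on bad rows.
    """
    if schema == "peaks":
        return read_peaks_bed(path)
    if schema not in _SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    df = _read_tsv(path, required=_SCHEMAS[schema])

    if schema == "expression":
        out = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                out.append(ExpressionRecord(str(row.gene_id), float(row.log2fc), float(row.pvalue)))
            except (ValueError, SchemaError) as exc:
                raise SchemaError(f"{path}: row {i}: {exc}") from exc
        return out
    if schema == "ipd":
        out = []
        for i, row in enumerate(df.itertuples(index=False), start=1):
            try:
                out.append(
                    IpdRecord(str(row.contig), int(row.position), str(row.strand),
                              float(row.ipd_ratio), float(row.qv))
                )
            except (ValueError, SchemaError) as exc:
                raise SchemaError(f"{path}: row {i}: {exc}") from exc
        return out
    if schema == "orthologs":
        return df[["group_id", "species_id", "gene_id"]].astype(str)
    # sites
    if "collection" not in df.columns:
        df = df.assign(collection="default")
    return df[["site", "collection"]].astype(str)


def read_sites(path: str | Path) -> dict[str, list[str]]:
    """Read aligned binding sites grouped by collection.

    Accepts either the headered TSV ``sites`` schema or a bare one-site-per-line
    file (all sites then fall in collection ``"default"``).
    """
    with open(path) as fh:
        first = fh.readline()
    if first.split("\t")[0].strip() == "site":
        df = read_table(path, "sites")
    else:
        rows = []
        with open(path) as fh:
            for line in fh:
                word = line.strip().upper()
                if word:
                    rows.append({"site": word, "collection": "default"})
        df = pd.DataFrame(rows, columns=["site", "collection"])
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["collection"], []).append(row["site"].upper())
    return out


def write_table(records, path: str | Path, float_format: str = "%.6g",
                schema: str | None = None) -> None:
    """Write homogeneous records as a TSV with header, in input order.

    Floats are rendered with 6 significant digits by default so that
    ``read_table`` round-trips to equal records.  An empty record list needs
    ``schema`` to name the header and yields a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records and hasattr(records[0], "__dataclass_fields__"):
            df = pd.DataFrame([asdict(r) for r in records])
        elif records:
            df = pd.DataFrame(records)
        elif schema is not None:
            df = pd.DataFrame(columns=_SCHEMAS[schema])
        else:
            raise ValueError("cannot infer header from an empty record list; pass schema=")
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_empty_table(schema: str, path: str | Path) -> None:
    """Header-only file for the named schema."""
    if schema == "peaks":
        Path(path).write_text("")
        return
    pd.DataFrame(columns=_SCHEMAS[schema]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------

def read_peaks_bed(path: str | Path) -> list[PeakRecord]:
    """BED4: chrom, start (0-based), end (exclusive), enrichment score."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: BED4 requires 4 columns")
            try:
                peaks.append(
                    PeakRecord(fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except (ValueError, SchemaError) as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_peaks_bed(peaks: Iterable[PeakRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.contig}\t{p.start}\t{p.end}\t{p.enrichment:.6g}\n")
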