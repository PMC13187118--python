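"""Readers and writers for every external dialect the pipeline touches.

Gene tables come in three dialects:

* ``gff3`` — 1-based inclusive coordinates; only rows whose feature type
  matches ``feature_type`` (default ``gene``) are kept, identified by the
  ``ID=`` attribute.
* ``tsv``  — four/five columns (gene_id, seq_id, start, end[, strand]),
  1-based inclusive.
* ``bed``  — BED4+ with optional strand in column 6; already 0-based
  half-open, passed through.

All gene intervals are normalised to 0-based half-open internally.
Protein hit tables are BLAST/DIAMOND tabular with a configurable column
layout (the tools let users choose their output fields, so the mapping is
explicit configuration rather than guesswork).
"""

from __future__ import annotations

import os
import tempfile
from collections import Counter
from typing import Iterable

import pandas as pd

from .errors import ConfigError, EmptyInputError, ParseError, ValidationError
from .tree import Phylogeny, grafen_branch_lengths, parse_newick, read_newick, write_newick  # noqa: F401
from .types import (
    BUSCO_STATUSES,
    BuscoRecord,
    GeneInterval,
    HitRecord,
    OrthoMatrix,
    validate_trait_table,
)

#: Default column order for hit tables: a DIAMOND/BLAST custom format with
#: query/subject lengths and percent-positives appended to the ids.
DEFAULT_HIT_COLUMNS = {
    "qseqid": 0,
    "sseqid": 1,
    "qlen": 2,
    "slen": 3,
    "length": 4,
    "ppos": 5,
    "sstart": 6,
    "send": 7,
}

_REQUIRED_HIT_FIELDS = tuple(DEFAULT_HIT_COLUMNS)


def _data_lines(path, comment: str | None = None):
    """Yield (lineno, stripped line) for non-blank, non-comment lines."""
    any_line = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if comment and line.startswith(comment):
                continue
            any_line = True
            yield lineno, line
    if not any_line:
        raise EmptyInputError("empty input", path=path)


# --------------------------------------------------------------- gene tables
def read_gene_table(path, format: str = "bed", feature_type: str = "gene") -> list[GeneInterval]:
    """Read a gene coordinate table in one of {gff3, bed, tsv}.

    GFF3/TSV coordinates (1-based inclusive) are converted to the internal
    0-based half-open convention; BED is passed through.  Rows whose
    converted interval is empty or inverted are rejected, as are duplicate
    gene ids.
    """
    if format not in ("gff3", "bed", "tsv"):
        raise ConfigError(f"unknown gene-table format {format!r}")
    genes: list[GeneInterval] = []
    seen: set[str] = set()
    comment = "#"
    for lineno, line in _data_lines(path, comment=comment):
        fields = line.split("\t")
        try:
            if format == "gff3":
                if len(fields) < 9:
                    raise ParseError("expected 9 GFF3 columns", path=path, line=lineno)
                if fields[2] != feature_type:
                    continue
                seq_id = fields[0]
                start = int(fields[3]) - 1  # to 0-based half-open
                end = int(fields[4])
                strand = fields[6] if fields[6] in ("+", "-") else "."
                attrs = dict(
                    kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
                )
                gene_id = attrs.get("ID")
                if gene_id is None:
                    raise ParseError("missing ID attribute", path=path, line=lineno)
            elif format == "tsv":
                if len(fields) < 4:
                    raise ParseError("expected >= 4 TSV columns", path=path, line=lineno)
                gene_id, seq_id = fields[0], fields[1]
                start = int(fields[2]) - 1
                end = int(fields[3])
                strand = fields[4] if len(fields) > 4 and fields[4] in ("+", "-") else "."
            else:  # bed
                if len(fields) < 4:
                    raise ParseError("expected >= 4 BED columns", path=path, line=lineno)
                seq_id = fields[0]
                start = int(fields[1])
                end = int(fields[2])
                gene_id = fields[3]
                strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
        except ValueError as exc:
            raise ParseError(f"malformed line: {exc}", path=path, line=lineno) from None
        if end <= start:
            raise ParseError(
                f"gene {gene_id!r}: empty/inverted interval ({start}, {end})",
                path=path,
                line=lineno,
            )
        if gene_id in seen:
            raise ValidationError(f"duplicate gene_id {gene_id!r} at {path} line {lineno}")
        seen.add(gene_id)
        genes.append(GeneInterval(gene_id, seq_id, start, end, strand))
    if not genes:
        raise EmptyInputError("no gene records", path=path)
    return genes


def write_gene_table(genes: Iterable[GeneInterval], path, format: str = "bed") -> None:
    """Write gene intervals as BED4+2 (0-based) or GFF3 (1-based inclusive)."""
    if format not in ("bed", "gff3"):
        raise ConfigError(f"unknown output format {format!r}")
    lines = []
    for g in genes:
        if format == "bed":
            lines.append(f"{g.seq_id}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}")
        else:
            strand = g.strand if g.strand in ("+", "-") else "."
            lines.append(
                f"{g.seq_id}\torthotraits\tgene\t{g.start + 1}\t{g.end}\t.\t{strand}\t.\tID={g.gene_id}"
            )
    atomic_write(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------- hit tables
def read_hit_table(path, column_spec: dict[str, int] | None = None) -> list[HitRecord]:
    """Read a BLAST/DIAMOND tabular hit file into HitRecords.

    ``column_spec`` maps field names (qseqid, sseqid, qlen, slen, length,
    ppos, sstart, send; optionally ``db``) to 0-based column indices.
    ``n_hsps_for_pair`` is the number of rows sharing a (query, subject)
    pair.
    """
    spec = dict(DEFAULT_HIT_COLUMNS) if column_spec is None else dict(column_spec)
    missing = [f for f in _REQUIRED_HIT_FIELDS if f not in spec]
    if missing:
        raise ConfigError(f"column_spec missing required fields: {missing}")
    rows = []
    for lineno, line in _data_lines(path, comment="#"):
        fields = line.split("\t")
        try:
            row = {
                name: fields[idx]
                for name, idx in spec.items()
                if idx < len(fields)
            }
            if len(row) < len(spec):
                raise ParseError("too few columns", path=path, line=lineno)
            rows.append((lineno, row))
        except IndexError:
            raise ParseError("too few columns", path=path, line=lineno) from None
    pair_counts = Counter((row["qseqid"], row["sseqid"]) for _, row in rows)
    hits = []
    for lineno, row in rows:
        try:
            sstart, send = int(row["sstart"]), int(row["send"])
        except ValueError as exc:
            raise ParseError(f"malformed line: {exc}", path=path, line=lineno) from None
        if sstart > send:
            raise ParseError(
                f"sstart {sstart} > send {send} (protein coordinates are ascending)",
                path=path,
                line=lineno,
            )
        try:
            hits.append(
                HitRecord(
                    query_id=row["qseqid"],
                    subject_id=row["sseqid"],
                    query_len=int(row["qlen"]),
                    subject_len=int(row["slen"]),
                    aln_len=int(row["length"]),
                    pct_positives=float(row["ppos"]),
                    subject_start=sstart,
                    subject_end=send,
                    n_hsps_for_pair=pair_counts[(row["qseqid"], row["sseqid"])],
                    db_tag=row.get("db", ""),
                )
            )
        except ValueError as exc:
            raise ParseError(f"malformed line: {exc}", path=path, line=lineno) from None
    return hits


# --------------------------------------------------------------- orthogroups
def read_orthogroups(path) -> OrthoMatrix:
    """Read an OrthoFinder-style ``Orthogroups.tsv``.

    First column is the orthogroup id, remaining columns one per taxon with
    comma-space-separated gene ids; empty cells mean zero genes.
    """
    lines = list(_data_lines(path))
    header = lines[0][1].split("\t")
    if len(header) < 2:
        raise ParseError("header must name at least one taxon", path=path, line=lines[0][0])
    taxa = header[1:]
    width = len(header)
    og_ids, counts, members = [], [], {}
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != width:
            raise ParseError(
                f"ragged row: {len(fields)} columns, expected {width}", path=path, line=lineno
            )
        og = fields[0]
        if og in members:
            raise ParseError(f"duplicate orthogroup id {og!r}", path=path, line=lineno)
        per_taxon = {}
        row_counts = []
        for taxon, cell in zip(taxa, fields[1:]):
            genes = [g.strip() for g in cell.split(",") if g.strip()] if cell.strip() else []
            per_taxon[taxon] = genes
            row_counts.append(len(genes))
        og_ids.append(og)
        counts.append(row_counts)
        members[og] = per_taxon
    if not og_ids:
        raise EmptyInputError("no orthogroup rows", path=path)
    frame = pd.DataFrame(counts, index=og_ids, columns=taxa, dtype=int)
    return OrthoMatrix(frame, members)


def write_orthogroups(matrix: OrthoMatrix, path) -> None:
    """Write an OrthoMatrix back out in the Orthogroups.tsv dialect."""
    lines = ["Orthogroup\t" + "\t".join(matrix.taxa)]
    for og in matrix.orthogroup_ids:
        cells = []
        for taxon in matrix.taxa:
            if matrix.members is not None:
                cells.append(", ".join(matrix.members.get(og, {}).get(taxon, [])))
            else:
                n = int(matrix.counts.at[og, taxon])
                cells.append(", ".join(f"{og}_{taxon}_{i}" for i in range(n)))
        lines.append(og + "\t" + "\t".join(cells))
    atomic_write(path, "\n".join(lines) + "\n")


# --------------------------------------------------------------------- BUSCO
def read_busco_table(path) -> list[BuscoRecord]:
    """Read a BUSCO v5 ``full_table.tsv``.

    Columns: busco_id, status, then (for non-Missing rows) sequence, start,
    end and further columns that are ignored.  Duplicated BUSCOs appear as
    several rows sharing an id.
    """
    records = []
    for lineno, line in _data_lines(path, comment="#"):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError("expected at least id and status", path=path, line=lineno)
        busco_id, status = fields[0], fields[1]
        if status not in BUSCO_STATUSES:
            raise ValidationError(
                f"unknown BUSCO status {status!r} at {path} line {lineno}"
            )
        if status == "Missing":
            records.append(BuscoRecord(busco_id, status))
            continue
        if len(fields) < 5:
            raise ParseError(
                f"status {status} requires sequence and coordinates", path=path, line=lineno
            )
        try:
            start, end = int(float(fields[3])), int(float(fields[4]))
        except ValueError as exc:
            raise ParseError(f"malformed coordinates: {exc}", path=path, line=lineno) from None
        records.append(BuscoRecord(busco_id, status, fields[2], start, end))
    if not records:
        raise EmptyInputError("no BUSCO rows", path=path)
    return records


# -------------------------------------------------------------- trait tables
def read_trait_table(path) -> pd.DataFrame:
    """Read a per-taxon trait TSV (taxon, diet, genome_span, extra metrics)."""
    try:
        table = pd.read_csv(path, sep="\t", dtype={"taxon": str})
    except pd.errors.EmptyDataError:
        raise EmptyInputError("empty input", path=path) from None
    if "taxon" not in table.columns:
        raise ParseError("trait table needs a 'taxon' column", path=path)
    if table.empty:
        raise EmptyInputError("no trait rows", path=path)
    table = table.set_index("taxon")
    return validate_trait_table(table)


# ------------------------------------------------------------------- helpers
def atomic_write(path, text: str) -> None:
    """Write ``text`` to ``path`` via a temp file + rename (no partial files)."""
    path = os.fspath(path)
    directory = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, prefix=".tmp-orthotraits-")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
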