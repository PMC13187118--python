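"""Shared domain types for the pipeline.

Coordinate convention: every :class:`GeneInterval` is stored 0-based,
half-open (BED-style), regardless of the dialect it was read from.
Protein alignment coordinates in :class:`HitRecord` stay 1-based inclusive
as in BLAST/DIAMOND tabular output.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

#: Strand symbols; "." means unknown (BED convention).
STRANDS = ("+", "-", ".")

BUSCO_STATUSES = ("Complete", "Duplicated", "Fragmented", "Missing")


@dataclass(frozen=True)
class GeneInterval:
    """One gene's genomic location (0-based, half-open)."""

    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if self.start < 0:
            raise ValidationError(
                f"gene {self.gene_id!r}: negative start {self.start}"
            )
        if self.end <= self.start:
            raise ValidationError(
                f"gene {self.gene_id!r}: empty or inverted interval "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValidationError(
                f"gene {self.gene_id!r}: bad strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class HitRecord:
    """One HSP from a protein similarity search (BLASTp/DIAMOND style).

    ``n_hsps_for_pair`` is the total number of HSP rows the source table
    holds for this (query, subject) pair; the gene-model tiering rules need
    it to recognise single-HSP alignments.
    """

    query_id: str
    subject_id: str
    query_len: int
    subject_len: int
    aln_len: int
    pct_positives: float
    subject_start: int
    subject_end: int
    n_hsps_for_pair: int = 1
    db_tag: str = ""

    def __post_init__(self):
        if not (1 <= self.subject_start <= self.subject_end <= self.subject_len):
            raise ValidationError(
                f"hit {self.query_id!r} vs {self.subject_id!r}: subject span "
                f"{self.subject_start}..{self.subject_end} outside "
                f"1..{self.subject_len} (protein coordinates are ascending)"
            )
        if not (0.0 <= self.pct_positives <= 100.0):
            raise ValidationError(
                f"hit {self.query_id!r} vs {self.subject_id!r}: "
                f"pct_positives {self.pct_positives} outside [0, 100]"
            )
        if self.n_hsps_for_pair < 1:
            raise ValidationError("n_hsps_for_pair must be >= 1")
        if self.query_len <= 0 or self.subject_len <= 0:
            raise ValidationError("protein lengths must be positive")

    @property
    def subject_coverage(self) -> float:
        """Fraction of the subject protein covered by this HSP."""
        return (self.subject_end - self.subject_start + 1) / self.subject_len


@dataclass(frozen=True)
class BuscoRecord:
    """One row of a BUSCO ``full_table.tsv``."""

    busco_id: str
    status: str
    seq_id: str | None = None
    start: int | None = None
    end: int | None = None

    def __post_init__(self):
        if self.status not in BUSCO_STATUSES:
            raise ValidationError(
                f"BUSCO {self.busco_id!r}: unknown status {self.status!r}"
            )
        has_coords = self.seq_id is not None and self.start is not None and self.end is not None
        if self.status == "Missing":
            if has_coords:
                raise ValidationError(
                    f"BUSCO {self.busco_id!r}: Missing entries carry no coordinates"
                )
        elif not has_coords:
            raise ValidationError(
                f"BUSCO {self.busco_id!r}: status {self.status} requires coordinates"
            )


@dataclass
class OrthoMatrix:
    """Orthogroup-by-taxon gene-count matrix.

    ``counts`` is a pandas DataFrame indexed by orthogroup id with one
    integer column per taxon.  ``members`` optionally maps
    orthogroup -> taxon -> list of gene ids; when present it must agree
    with ``counts``.
    """

    counts: pd.DataFrame
    members: dict[str, dict[str, list[str]]] | None = None

    def __post_init__(self):
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate orthogroup id {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("orthogroup counts must be non-negative")
        if (self.counts.sum(axis=1) == 0).any():
            empty = self.counts.index[self.counts.sum(axis=1) == 0][0]
            raise ValidationError(f"orthogroup {empty!r} has no genes in any taxon")
        if self.members is not None:
            for og, per_taxon in self.members.items():
                for taxon, genes in per_taxon.items():
                    if self.counts.at[og, taxon] != len(genes):
                        raise ValidationError(
                            f"orthogroup {og!r}, taxon {taxon!r}: count "
                            f"{self.counts.at[og, taxon]} != {len(genes)} listed genes"
                        )

    @property
    def orthogroup_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def restrict(self, orthogroups) -> "OrthoMatrix":
        """Sub-matrix for the given orthogroup ids (order preserved)."""
        ogs = [og for og in orthogroups]
        missing = [og for og in ogs if og not in self.counts.index]
        if missing:
            raise ValidationError(f"unknown orthogroups: {missing}")
        members = None
        if self.members is not None:
            members = {og: self.members[og] for og in ogs if og in self.members}
        return OrthoMatrix(self.counts.loc[ogs].copy(), members)


DIETS = ("herbivore", "predator", "omnivore", "hematophagous", "unknown")


def validate_trait_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-taxon trait table (index: taxon; columns incl. diet, genome_span)."""
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()][0]
        raise ValidationError(f"duplicate taxon {dup!r} in trait table")
    if "diet" in table.columns:
        bad = set(table["diet"].dropna()) - set(DIETS)
        if bad:
            raise ValidationError(f"unknown diet classes: {sorted(bad)}")
    if "genome_span" in table.columns:
        spans = table["genome_span"].dropna()
        if (spans <= 0).any():
            raise ValidationError("genome_span must be positive")
    return table
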