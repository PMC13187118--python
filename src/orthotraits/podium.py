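"""Homology-tiered classification of predicted gene models.

Predicted proteins are compared against reference protein databases and
sorted into quality tiers by how convincingly a reference protein supports
them:

* **gold** — query >= 150 aa, a single-HSP alignment to a subject >= 150 aa
  with >= 75% positive-scoring aligned residues covering >= 90% of the
  subject's length;
* **silver** — query >= 100 aa with a hit covering >= 75% of a subject
  >= 100 aa long;
* **bronze** — any hit covering >= 30% of its subject;
* **non-podium** — everything else (with or without a database hit).

Subject coverage is the subject-aligned span divided by the subject length,
so gapped alignment columns cannot inflate it.  A gene's tier is the best
tier any single hit earns; hits from different databases are pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .errors import ValidationError
from .types import HitRecord

TIERS = ("gold", "silver", "bronze", "non_podium")


@dataclass(frozen=True)
class TierThresholds:
    """All tunable cut-offs of the tiering rules (defaults as published)."""

    gold_min_query_len: int = 150
    gold_min_subject_len: int = 150
    gold_min_ppos: float = 75.0
    gold_min_coverage: float = 0.90
    silver_min_query_len: int = 100
    silver_min_subject_len: int = 100
    silver_min_coverage: float = 0.75
    bronze_min_coverage: float = 0.30


DEFAULT_THRESHOLDS = TierThresholds()


@dataclass(frozen=True)
class TierAssignment:
    gene_id: str
    tier: str
    has_any_hit: bool
    supporting_subject: str | None = None

    def __post_init__(self):
        if self.tier not in TIERS:
            raise ValidationError(f"unknown tier {self.tier!r}")
        if self.tier != "non_podium" and not self.has_any_hit:
            raise ValidationError("podium tier requires a hit")
        if (self.supporting_subject is None) != (self.tier == "non_podium"):
            raise ValidationError("supporting_subject present iff podium tier")


@dataclass
class TranchePartition:
    """Per-tier counts and fractions over the length-bounded gene set."""

    counts: dict[str, int]
    total: int
    fractions: dict[str, float]
    non_podium_with_hit: int
    non_podium_with_hit_fraction: float

    def percent(self, tier: str, ndigits: int = 1) -> float:
        """Tier share of the total, as a percentage rounded to ``ndigits``."""
        return round(100.0 * self.fractions[tier], ndigits)

    @property
    def non_podium_with_hit_percent(self) -> float:
        return round(100.0 * self.non_podium_with_hit_fraction, 1)


def length_filter(
    protein_lengths: Mapping[str, int], min_len: int = 100, max_len: int = 6000
) -> set[str]:
    """Genes whose protein length is within [min_len, max_len], inclusive."""
    if min_len <= 0 or max_len < min_len:
        raise ValidationError(f"bad length bounds [{min_len}, {max_len}]")
    bad = [g for g, n in protein_lengths.items() if n <= 0]
    if bad:
        raise ValidationError(f"non-positive protein length for {bad[:3]}")
    return {g for g, n in protein_lengths.items() if min_len <= n <= max_len}


def _hit_qualifies(hit: HitRecord, query_len: int, tier: str, th: TierThresholds) -> bool:
    cov = hit.subject_coverage
    if tier == "gold":
        return (
            query_len >= th.gold_min_query_len
            and hit.subject_len >= th.gold_min_subject_len
            and hit.n_hsps_for_pair == 1
            and hit.pct_positives >= th.gold_min_ppos
            and cov >= th.gold_min_coverage
        )
    if tier == "silver":
        return (
            query_len >= th.silver_min_query_len
            and hit.subject_len >= th.silver_min_subject_len
            and cov >= th.silver_min_coverage
        )
    if tier == "bronze":
        return cov >= th.bronze_min_coverage
    raise ValidationError(f"unknown tier {tier!r}")


def classify_gene(
    gene_id: str,
    query_len: int,
    hits: Iterable[HitRecord],
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> TierAssignment:
    """Assign the best tier any single hit earns for this gene.

    The supporting subject is the qualifying hit with the highest subject
    coverage at the winning tier, ties broken lexicographically on
    subject id.
    """
    hits = list(hits)
    for h in hits:
        if h.query_id != gene_id:
            raise ValidationError(
                f"hit query {h.query_id!r} does not belong to gene {gene_id!r}"
            )
    for tier in ("gold", "silver", "bronze"):
        qualifying = [h for h in hits if _hit_qualifies(h, query_len, tier, thresholds)]
        if qualifying:
            best = max(qualifying, key=lambda h: (h.subject_coverage, _NegStr(h.subject_id)))
            return TierAssignment(gene_id, tier, True, best.subject_id)
    return TierAssignment(gene_id, "non_podium", bool(hits), None)


class _NegStr:
    """Orders strings descending inside a max() key (ascending tie-break)."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other) -> bool:
        return self.s == other.s


def partition_report(assignments: Iterable[TierAssignment]) -> TranchePartition:
    """Tranche partition: per-tier counts and fractions of the total, plus the
    share of non-podium genes that still had some database hit."""
    assignments = list(assignments)
    if not assignments:
        raise ValidationError("no assignments to summarise")
    counts = {tier: 0 for tier in TIERS}
    np_with_hit = 0
    for a in assignments:
        counts[a.tier] += 1
        if a.tier == "non_podium" and a.has_any_hit:
            np_with_hit += 1
    total = len(assignments)
    fractions = {tier: counts[tier] / total for tier in TIERS}
    np_frac = np_with_hit / counts["non_podium"] if counts["non_podium"] else 0.0
    return TranchePartition(counts, total, fractions, np_with_hit, np_frac)
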