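"""Gap-based gene-cluster detection and summary statistics.

Two genes belong to the same cluster when they lie on the same sequence and
the gap between their intervals is at most ``max_gap`` base pairs (35 kbp by
default, the conventional window for calling tandem arrays in hemipteran
genomes).  The rule is transitive bedtools-``merge -d`` semantics: chains of
genes each within the gap of a neighbour merge into one cluster even if the
chain ends are farther apart, and overlapping genes (gap <= 0) always merge.

Two analysis modes are exposed: pooling genes from many expanded orthogroups
into one clustering pass, and clustering each gene family independently.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ConfigError, ValidationError
from .types import GeneInterval

DEFAULT_MAX_GAP = 35_000


@dataclass(frozen=True)
class GeneCluster:
    seq_id: str
    span_start: int
    span_end: int
    member_gene_ids: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.member_gene_ids)


@dataclass
class ClusterSummary:
    """Per-taxon cluster statistics (matches the published table layout)."""

    n_clusters: int
    n_single: int
    n_clustered: int
    ratio: float | None  # n_single / n_clustered, None when nothing clustered
    largest_cluster_size: int
    average_cluster_size: float | None  # mean over clusters of size >= 2

    @property
    def ratio_report(self) -> str:
        return "NA" if self.ratio is None else f"{self.ratio:.4f}"

    @property
    def average_report(self) -> str:
        return "NA" if self.average_cluster_size is None else f"{self.average_cluster_size:.2f}"


def cluster_genes(
    genes: Iterable[GeneInterval], max_gap: int = DEFAULT_MAX_GAP
) -> list[GeneCluster]:
    """Group genes into proximity clusters (singletons are size-1 clusters).

    Per sequence, genes are sorted by start and a new cluster opens whenever
    the gap to the running maximum end exceeds ``max_gap``.
    """
    if max_gap < 0:
        raise ConfigError(f"max_gap must be non-negative, got {max_gap}")
    by_seq: dict[str, list[GeneInterval]] = {}
    for g in genes:
        by_seq.setdefault(g.seq_id, []).append(g)
    clusters: list[GeneCluster] = []
    for seq_id in sorted(by_seq):
        block = sorted(by_seq[seq_id], key=lambda g: (g.start, g.end, g.gene_id))
        current: list[GeneInterval] = []
        max_end = None
        for g in block:
            if current and g.start - max_end > max_gap:
                clusters.append(_finish(seq_id, current))
                current = []
                max_end = None
            current.append(g)
            max_end = g.end if max_end is None else max(max_end, g.end)
        if current:
            clusters.append(_finish(seq_id, current))
    return clusters


def _finish(seq_id: str, members: Sequence[GeneInterval]) -> GeneCluster:
    return GeneCluster(
        seq_id=seq_id,
        span_start=min(g.start for g in members),
        span_end=max(g.end for g in members),
        member_gene_ids=tuple(g.gene_id for g in members),
    )


def summarize_clusters(clusters: Sequence[GeneCluster]) -> ClusterSummary:
    """Singleton/clustered gene counts, their ratio, and cluster sizes.

    ``ratio`` is singleton genes divided by genes inside size->=2 clusters
    (reported to 4 decimals); ``average_cluster_size`` averages only clusters
    of size >= 2.
    """
    if not clusters:
        raise ValidationError("no clusters to summarise")
    sizes = [c.size for c in clusters]
    n_single = sum(1 for s in sizes if s == 1)
    multi = [s for s in sizes if s >= 2]
    n_clustered = sum(multi)
    ratio = None if n_clustered == 0 else n_single / n_clustered
    average = None if not multi else n_clustered / len(multi)
    return ClusterSummary(
        n_clusters=len(clusters),
        n_single=n_single,
        n_clustered=n_clustered,
        ratio=ratio,
        largest_cluster_size=max(sizes),
        average_cluster_size=average,
    )


def family_cluster_report(
    families: Mapping[str, Sequence[GeneInterval]],
    max_gap: int = DEFAULT_MAX_GAP,
) -> dict[str, dict[str, int]]:
    """Cluster each gene family independently; count clustered vs singleton genes.

    Families must be disjoint gene sets.  Returns, per family, the number of
    genes inside multi-gene clusters and the number of singletons.
    """
    seen: dict[str, str] = {}
    for fam, genes in families.items():
        for g in genes:
            if g.gene_id in seen:
                raise ValidationError(
                    f"gene {g.gene_id!r} assigned to families "
                    f"{seen[g.gene_id]!r} and {fam!r}"
                )
            seen[g.gene_id] = fam
    report = {}
    for fam, genes in families.items():
        clusters = cluster_genes(genes, max_gap=max_gap)
        clustered = sum(c.size for c in clusters if c.size >= 2)
        single = sum(1 for c in clusters if c.size == 1)
        report[fam] = {"clustered": clustered, "single": single}
    return report
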