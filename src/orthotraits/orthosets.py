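"""Trait-group presence/absence analysis of orthogroups.

Two questions are answered here.  First, which orthogroups are present (at
least one gene) in *every* member of a named taxon group — e.g. all
predators, all herbivores, all members of an infraorder — and how those four
core sets overlap (a 4-set Venn decomposition).  Second, for orthogroups of
one gene family that contain a focal taxon, which exact combination of
comparator taxa co-occurs with it (the combination tally).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError
from .types import OrthoMatrix


@dataclass(frozen=True)
class GroupDefinition:
    name: str
    member_taxa: frozenset[str]

    def __post_init__(self):
        if not self.member_taxa:
            raise ValidationError(f"group {self.name!r} has no taxa")


@dataclass
class CombinationTally:
    """Counts of focal-containing orthogroups by comparator combination."""

    focal_taxon: str
    comparators: tuple[str, ...]
    counts: dict[frozenset[str], int]
    total: int

    def count_for(self, *comparators: str) -> int:
        return self.counts.get(frozenset(comparators), 0)

    @property
    def all_count(self) -> int:
        """Orthogroups containing the focal taxon and every comparator."""
        return self.counts.get(frozenset(self.comparators), 0)


def group_core(matrix: OrthoMatrix, group: GroupDefinition) -> set[str]:
    """Orthogroups with at least one gene in every taxon of the group."""
    unknown = group.member_taxa - set(matrix.taxa)
    if unknown:
        raise ValidationError(f"group {group.name!r}: unknown taxa {sorted(unknown)}")
    sub = matrix.counts[list(group.member_taxa)]
    mask = (sub >= 1).all(axis=1)
    return set(sub.index[mask])


def venn_counts(core_sets: Mapping[str, set[str]]) -> dict[frozenset[str], int]:
    """Exclusive-region counts of a standard Venn decomposition.

    For every nonempty subset S of set names, the returned count is the
    number of elements in all sets of S and in none of the others.
    """
    names = list(core_sets)
    regions: dict[frozenset[str], int] = {}
    universe = set().union(*core_sets.values()) if core_sets else set()
    membership: dict[str, frozenset[str]] = {}
    for el in universe:
        membership[el] = frozenset(n for n in names if el in core_sets[n])
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            regions[frozenset(combo)] = 0
    for mask in membership.values():
        regions[mask] += 1
    return regions


def combination_tally(
    matrix: OrthoMatrix,
    focal_taxon: str,
    comparators: Sequence[str],
    orthogroups: Iterable[str] | None = None,
) -> CombinationTally:
    """Tally focal-containing orthogroups by their comparator combination.

    Orthogroups without a focal-taxon gene are dropped; each kept orthogroup
    is labelled by the exact subset of comparators that also contain it
    (the full set is the "All" row of the published table).
    """
    comparators = tuple(comparators)
    if focal_taxon in comparators:
        raise ValidationError("focal taxon cannot be its own comparator")
    for t in (focal_taxon, *comparators):
        if t not in matrix.taxa:
            raise ValidationError(f"unknown taxon {t!r}")
    sub = matrix if orthogroups is None else matrix.restrict(orthogroups)
    counts: dict[frozenset[str], int] = {}
    total = 0
    for og in sub.orthogroup_ids:
        if sub.counts.at[og, focal_taxon] < 1:
            continue
        present = frozenset(t for t in comparators if sub.counts.at[og, t] >= 1)
        counts[present] = counts.get(present, 0) + 1
        total += 1
    return CombinationTally(focal_taxon, comparators, counts, total)
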