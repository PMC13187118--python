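"""BUSCO-anchored synteny links between two assemblies.

A synteny link is a BUSCO gene that is complete and single-copy in both
assemblies; joining its coordinates in each yields the anchor set behind a
ribbon/ideogram synteny plot.  The chromosome contingency matrix counts
links per (chromosome A, chromosome B) pair and summarises, per chromosome
of one assembly, how many chromosomes of the other it maps to — the signal
used to spot large-scale rearrangements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import ValidationError
from .types import BuscoRecord


@dataclass(frozen=True)
class SyntenyLink:
    busco_id: str
    seq_a: str
    start_a: int
    end_a: int
    seq_b: str
    start_b: int
    end_b: int


def _single_complete(records: Sequence[BuscoRecord]) -> dict[str, BuscoRecord]:
    """BUSCO ids with exactly one Complete record (and no other record)."""
    by_id: dict[str, list[BuscoRecord]] = {}
    for r in records:
        by_id.setdefault(r.busco_id, []).append(r)
    return {
        bid: recs[0]
        for bid, recs in by_id.items()
        if len(recs) == 1 and recs[0].status == "Complete"
    }


def link_buscos(
    table_a: Sequence[BuscoRecord], table_b: Sequence[BuscoRecord]
) -> list[SyntenyLink]:
    """Pair BUSCOs complete and single-copy in both assemblies.

    Output is sorted by (seq_a, start_a).  Duplicated or fragmented ids in
    either table are excluded.
    """
    a = _single_complete(table_a)
    b = _single_complete(table_b)
    links = [
        SyntenyLink(
            busco_id=bid,
            seq_a=a[bid].seq_id,
            start_a=a[bid].start,
            end_a=a[bid].end,
            seq_b=b[bid].seq_id,
            start_b=b[bid].start,
            end_b=b[bid].end,
        )
        for bid in a.keys() & b.keys()
    ]
    links.sort(key=lambda l: (l.seq_a, l.start_a, l.busco_id))
    return links


def chromosome_contingency(links: Sequence[SyntenyLink]) -> pd.DataFrame:
    """Link counts per (seq_a, seq_b) chromosome pair (rows: A, columns: B)."""
    if not links:
        return pd.DataFrame(dtype=int)
    frame = pd.DataFrame(
        {"seq_a": [l.seq_a for l in links], "seq_b": [l.seq_b for l in links]}
    )
    return pd.crosstab(frame["seq_a"], frame["seq_b"])


def distinct_partner_counts(
    contingency: pd.DataFrame, min_links: int = 1
) -> pd.Series:
    """Per chromosome of A, the number of distinct B chromosomes hit by at
    least ``min_links`` links."""
    if min_links < 1:
        raise ValidationError("min_links must be >= 1")
    if contingency.empty:
        return pd.Series(dtype=int)
    return (contingency >= min_links).sum(axis=1)
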