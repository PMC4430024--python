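"""Aggregate motif hits into per-promoter, per-family count tables and
detect overlapping binding-site occurrences.

Counting convention: the headline "family count" is the number of *distinct
hit intervals* (the same interval hit on both strands counts once) from any
member of the family. A parallel raw-occurrence count (all hits, both
strands) is reported alongside, since published count tables are ambiguous
about strand deduplication; reporting both makes either reading
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .motif import MotifHit


@dataclass(frozen=True)
class OverlapGroup:
    """A maximal set of >= 2 hits chained by >= 1 bp pairwise overlaps."""

    hits: tuple[MotifHit, ...]
    cross_family: bool

    @property
    def span(self) -> tuple[int, int]:
        return min(h.start for h in self.hits), max(h.end for h in self.hits)


def find_overlaps(hits: Sequence[MotifHit]) -> list[OverlapGroup]:
    """Group hits on one sequence that share at least 1 bp (any strand).

    Groups are connected components of the interval-overlap relation;
    singleton groups are omitted. ``cross_family`` flags groups mixing
    members of more than one family.
    """
    ordered = sorted(hits, key=lambda h: (h.start, h.end, h.strand, h.tf_name))
    groups: list[OverlapGroup] = []
    current: list[MotifHit] = []
    current_end = -1
    for h in ordered:
        if current and h.start < current_end:
            current.append(h)
            current_end = max(current_end, h.end)
        else:
            if len(current) > 1:
                groups.append(_make_group(current))
            current = [h]
            current_end = h.end
    if len(current) > 1:
        groups.append(_make_group(current))
    return groups


def _make_group(hits: list[MotifHit]) -> OverlapGroup:
    families = {h.family for h in hits}
    return OverlapGroup(hits=tuple(hits), cross_family=len(families) > 1)


def count_by_family(
    hits: Sequence[MotifHit],
    family_map: dict[str, str],
    members_of_interest: Sequence[str] = (),
) -> dict[str, float]:
    """One count-table row for the hits of a single promoter.

    Emits, per family, the distinct-interval count and the raw occurrence
    count; per requested member, an ``of_which_<member>`` distinct-interval
    count; per TF, a raw count; and the number of distinct intervals that
    overlap another distinct interval (the "overlapping occurrences").
    """
    for h in hits:
        if h.tf_name not in family_map:
            raise KeyError(f"TF {h.tf_name!r} missing from family map")
    row: dict[str, float] = {}
    families = sorted(set(family_map.values()))
    for fam in families:
        fam_hits = [h for h in hits if family_map[h.tf_name] == fam]
        distinct = {(h.start, h.end) for h in fam_hits}
        row[fam] = len(distinct)
        row[f"{fam}_raw"] = len(fam_hits)
    for member in members_of_interest:
        distinct = {(h.start, h.end) for h in hits if h.tf_name == member}
        row[f"of_which_{member}"] = len(distinct)
    for tf in sorted({h.tf_name for h in hits}):
        row[f"tf_{tf}"] = sum(1 for h in hits if h.tf_name == tf)
    # distinct intervals participating in any >=1 bp overlap
    intervals = sorted({(h.start, h.end) for h in hits})
    overlapping = set()
    for i, (s1, e1) in enumerate(intervals):
        for s2, e2 in intervals[i + 1 :]:
            if s2 >= e1:
                break
            overlapping.add((s1, e1))
            overlapping.add((s2, e2))
    row["overlapping_occurrences"] = len(overlapping)
    return row


def build_dataset_table(rows: Iterable[dict]) -> pd.DataFrame:
    """Assemble per-promoter rows (each carrying ``gene``, ``species``,
    ``variant`` keys) into a stable, TSV-serializable table.

    Rows are ordered by (gene, species, variant); duplicate keys are an
    error. Missing count columns are filled with 0.
    """
    rows = list(rows)
    key_cols = ["gene", "species", "variant"]
    for r in rows:
        missing = [k for k in key_cols if k not in r]
        if missing:
            raise ValueError(f"row missing key column(s) {missing}: {r}")
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=key_cols)
    keys = df[key_cols].apply(tuple, axis=1)
    dup = keys[keys.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate (gene, species, variant) key: {dup.iloc[0]}")
    count_cols = [c for c in df.columns if c not in key_cols]
    df[count_cols] = df[count_cols].fillna(0)
    int_like = [c for c in count_cols if (df[c] == df[c].round()).all()]
    df[int_like] = df[int_like].astype(int)
    return (
        df.sort_values(key_cols)
        .reset_index(drop=True)[key_cols + sorted(count_cols)]
    )


def overlap_groups_to_json(groups: Sequence[OverlapGroup]) -> list[dict]:
    return [
        {
            "span": list(g.span),
            "cross_family": g.cross_family,
            "hits": [
                {
                    "tf": h.tf_name,
                    "family": h.family,
                    "start": h.start,
                    "end": h.end,
                    "strand": h.strand,
                }
                for h in g.hits
            ],
        }
        for g in groups
    ]
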