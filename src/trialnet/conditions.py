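"""Region-stratified condition rankings for multinational studies.

A study counts toward a region if at least one of its countries lies there,
so one study can appear in several regions' tables. Within a region a study
counts once toward each of its listed conditions. The denominator for
proportions is the number of multinational studies touching the region.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .registry_io import RegionMap, StudyRecord, assign_region


@dataclass(frozen=True)
class ConditionRow:
    rank: int
    condition: str
    count: int
    proportion: float


#: region -> ranked rows (ties at the cutoff rank are reported jointly)
ConditionRegionTable = dict[str, list[ConditionRow]]


def normalize_condition(
    raw: str, synonyms: Mapping[str, str] | None = None
) -> str:
    """Case-fold and trim a condition label; apply an optional synonym map."""
    label = raw.strip().casefold()
    if synonyms:
        label = synonyms.get(label, label)
    return label


def condition_region_table(
    studies: Iterable[StudyRecord],
    region_map: RegionMap,
    k: int = 5,
    *,
    synonyms: Mapping[str, str] | None = None,
    strict: bool = False,
) -> ConditionRegionTable:
    """Rank the top-k conditions per region by multinational-study count.

    Rows at the cutoff rank that tie on count are all included. Proportions
    are counts over the region's multinational-study total.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    region_condition_counts: dict[str, Counter[str]] = {}
    region_study_counts: Counter[str] = Counter()
    for study in studies:
        regions = {
            assign_region(c, region_map, strict=strict) for c in study.countries
        }
        conditions = {normalize_condition(c, synonyms) for c in study.conditions}
        for region in regions:
            region_study_counts[region] += 1
            counts = region_condition_counts.setdefault(region, Counter())
            for condition in conditions:
                counts[condition] += 1

    table: ConditionRegionTable = {}
    for region in sorted(region_condition_counts):
        counts = region_condition_counts[region]
        denom = region_study_counts[region]
        ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if len(ranked) > k:
            cutoff = ranked[k - 1][1]
            ranked = [kv for i, kv in enumerate(ranked) if i < k or kv[1] == cutoff]
        rows = []
        rank = 0
        prev_count = None
        for i, (condition, count) in enumerate(ranked, start=1):
            if count != prev_count:
                rank = i
                prev_count = count
            rows.append(ConditionRow(rank, condition, count, count / denom))
        table[region] = rows
    return table


def write_condition_table_csv(table: ConditionRegionTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["region", "rank", "condition", "count", "proportion"])
        for region in sorted(table):
            for row in table[region]:
                writer.writerow(
                    [region, row.rank, row.condition, row.count, f"{row.proportion:.6f}"]
                )
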