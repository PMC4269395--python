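"""Connectivity and participation summaries of the co-participation network.

Country-level "connections" here means weighted node incidence (node size);
distinct-neighbor counts and study-participation counts are exposed as
separately named quantities because the three do not coincide.

Region attribution: an edge's weight is divided between its two endpoints'
regions. Under ``endpoint_half`` each region receives weight/2 (masses sum
to the total weight); under ``endpoint_full`` each receives the full weight
(masses sum to twice the total and read as incidence counts). Shares sum to
1 under both policies.
"""

from __future__ import annotations

import csv
import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .network_builder import TrialNetwork, WeightedEdge
from .registry_io import RegionMap, StudyRecord, assign_region

ATTRIBUTION_POLICIES = ("endpoint_half", "endpoint_full")


@dataclass
class ConnectivityReport:
    total_weight: int
    country_totals: dict[str, tuple[int, float]]
    region_totals: dict[str, tuple[float, float]]
    cross_region_share: float | None
    top_edges: list[WeightedEdge]
    attribution_policy: str = "endpoint_half"


@dataclass
class ParticipationReport:
    n_multinational: int
    region_counts: dict[str, int] = field(default_factory=dict)
    region_proportions: dict[str, float] = field(default_factory=dict)
    country_counts: dict[str, int] = field(default_factory=dict)


def total_connections(net: TrialNetwork) -> int:
    """Total weight of the network: sum of all edge weights."""
    return net.total_weight


def country_connection_totals(net: TrialNetwork) -> dict[str, tuple[int, float]]:
    """Per-country weighted totals and shares of the endpoint-incidence mass.

    Shares are node_size / (2 * total weight) and sum to 1.
    """
    total = total_connections(net)
    if total == 0:
        return {}
    return {
        country: (size, size / (2 * total))
        for country, size in sorted(net.nodes.items())
    }


def distinct_neighbor_counts(net: TrialNetwork) -> dict[str, int]:
    """Unweighted degree: number of distinct partner countries per country."""
    deg: Counter[str] = Counter()
    for edge in net.edges:
        deg[edge.pair.u] += 1
        deg[edge.pair.v] += 1
    return dict(sorted(deg.items()))


def region_connection_totals(
    net: TrialNetwork,
    region_map: RegionMap,
    policy: str = "endpoint_half",
    *,
    strict: bool = False,
) -> dict[str, tuple[float, float]]:
    """Attribute edge weight to the regions of the edge endpoints."""
    if policy not in ATTRIBUTION_POLICIES:
        raise ValueError(f"unknown attribution policy {policy!r}")
    per_endpoint = 0.5 if policy == "endpoint_half" else 1.0
    masses: defaultdict[str, float] = defaultdict(float)
    for edge in net.edges:
        for country in edge.pair:
            region = assign_region(country, region_map, strict=strict)
            masses[region] += per_endpoint * edge.weight
    grand = sum(masses.values())
    if grand == 0:
        return {}
    return {
        region: (mass, mass / grand) for region, mass in sorted(masses.items())
    }


def cross_region_share(
    net: TrialNetwork, region_map: RegionMap, *, strict: bool = False
) -> float:
    """Fraction of total edge weight on edges whose endpoints' regions differ."""
    total = total_connections(net)
    if total == 0:
        raise ValueError("cross-region share undefined for an empty network")
    cross = sum(
        e.weight
        for e in net.edges
        if assign_region(e.pair.u, region_map, strict=strict)
        != assign_region(e.pair.v, region_map, strict=strict)
    )
    return cross / total


def top_edges(net: TrialNetwork, k: int) -> list[WeightedEdge]:
    """The k strongest connections, ties broken by canonical pair order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(net.edges, key=lambda e: (-e.weight, e.pair))
    return ranked[:k]


def participation_report(
    studies: Iterable[StudyRecord],
    region_map: RegionMap,
    *,
    strict: bool = False,
) -> ParticipationReport:
    """Count multinational studies touching each region and each country.

    A study counts toward every region in which at least one of its
    countries lies, so region proportions can sum to more than 1.
    """
    studies = list(studies)
    region_counts: Counter[str] = Counter()
    country_counts: Counter[str] = Counter()
    for study in studies:
        regions = set()
        for country in study.countries:
            country_counts[country] += 1
            regions.add(assign_region(country, region_map, strict=strict))
        for region in regions:
            region_counts[region] += 1
    n = len(studies)
    return ParticipationReport(
        n_multinational=n,
        region_counts=dict(sorted(region_counts.items())),
        region_proportions={
            r: c / n for r, c in sorted(region_counts.items())
        }
        if n
        else {},
        country_counts=dict(sorted(country_counts.items())),
    )


def connectivity_report(
    net: TrialNetwork,
    region_map: RegionMap,
    *,
    policy: str = "endpoint_half",
    k: int = 10,
    strict: bool = False,
) -> ConnectivityReport:
    total = total_connections(net)
    return ConnectivityReport(
        total_weight=total,
        country_totals=country_connection_totals(net),
        region_totals=region_connection_totals(net, region_map, policy, strict=strict),
        cross_region_share=(
            cross_region_share(net, region_map, strict=strict) if total else None
        ),
        top_edges=top_edges(net, k) if net.edges else [],
        attribution_policy=policy,
    )


def write_connectivity_json(report: ConnectivityReport, path: str | Path) -> None:
    payload = {
        "total_weight": report.total_weight,
        "attribution_policy": report.attribution_policy,
        "cross_region_share": report.cross_region_share,
        "country_totals": {
            c: {"weighted_total": w, "share": s}
            for c, (w, s) in report.country_totals.items()
        },
        "region_totals": {
            r: {"mass": m, "share": s} for r, (m, s) in report.region_totals.items()
        },
        "top_edges": [
            {"source": e.pair.u, "target": e.pair.v, "weight": e.weight}
            for e in report.top_edges
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_country_totals_csv(report: ConnectivityReport, path: str | Path) -> None:
    rows = sorted(
        report.country_totals.items(), key=lambda kv: (-kv[1][0], kv[0])
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["country", "weighted_total", "share"])
        for country, (weight, share) in rows:
            writer.writerow([country, weight, f"{share:.6f}"])


def write_participation_csv(report: ParticipationReport, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["scope", "name", "count", "proportion"])
        for region, count in report.region_counts.items():
            writer.writerow(
                ["region", region, count, f"{report.region_proportions[region]:.6f}"]
            )
        n = report.n_multinational
        for country, count in report.country_counts.items():
            writer.writerow(
                ["country", country, count, f"{count / n:.6f}" if n else ""]
            )
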