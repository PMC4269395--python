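"""Build the weighted country co-participation network.

Every multinational study contributes one connection instance per unordered
pair of its participating countries. All instances are pooled into a master
list (a multiset of pairs); collapsing the multiset gives each distinct pair
an integer weight equal to the number of studies the two countries shared.
Node sizes are the weighted totals of incident connections.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from .registry_io import RegionMap, StudyRecord, assign_region


@dataclass(frozen=True, order=True)
class CountryPair:
    """An unordered pair of distinct countries, stored in canonical order."""

    u: str
    v: str

    def __post_init__(self) -> None:
        if self.u == self.v:
            raise ValueError(f"self-pair {self.u!r}")
        if self.u > self.v:
            object.__setattr__(self, "u", self.v)
            object.__setattr__(self, "v", self.u)

    @classmethod
    def of(cls, a: str, b: str) -> "CountryPair":
        return cls(*sorted((a, b)))

    def __iter__(self) -> Iterator[str]:
        return iter((self.u, self.v))


@dataclass(frozen=True)
class WeightedEdge:
    """A country pair with the number of studies the two countries shared."""

    pair: CountryPair
    weight: int

    def __post_init__(self) -> None:
        if self.weight < 1:
            raise ValueError("edge weight must be a positive integer")


class MasterList:
    """Multiset of connection instances: one entry per (study, pair)."""

    def __init__(self, counts: Counter[CountryPair] | None = None):
        self.counts: Counter[CountryPair] = Counter(counts or {})

    def add(self, pair: CountryPair, n: int = 1) -> None:
        self.counts[pair] += n

    def __len__(self) -> int:
        return sum(self.counts.values())

    def __iter__(self) -> Iterator[CountryPair]:
        for pair in sorted(self.counts):
            yield from [pair] * self.counts[pair]

    def multiplicity(self, pair: CountryPair) -> int:
        return self.counts.get(pair, 0)

    def __eq__(self, other) -> bool:
        return isinstance(other, MasterList) and self.counts == other.counts


@dataclass
class TrialNetwork:
    """The integrated weighted graph plus per-node weighted totals.

    Invariant: sum of node sizes equals twice the sum of edge weights.
    Isolated nodes do not exist — every node is an endpoint of some edge.
    """

    nodes: dict[str, int] = field(default_factory=dict)
    edges: list[WeightedEdge] = field(default_factory=list)

    @property
    def total_weight(self) -> int:
        return sum(e.weight for e in self.edges)

    def edge_weight(self, a: str, b: str) -> int:
        pair = CountryPair.of(a, b)
        for edge in self.edges:
            if edge.pair == pair:
                return edge.weight
        return 0

    def to_networkx(self, region_map: RegionMap | None = None) -> nx.Graph:
        g = nx.Graph()
        for country, size in sorted(self.nodes.items()):
            attrs = {"size": size}
            if region_map is not None:
                attrs["region"] = assign_region(country, region_map)
            g.add_node(country, **attrs)
        for edge in sorted(self.edges, key=lambda e: e.pair):
            g.add_edge(edge.pair.u, edge.pair.v, weight=edge.weight)
        return g


def extract_pairs(study: StudyRecord) -> set[CountryPair]:
    """All C(k, 2) unordered pairings of a multinational study's countries."""
    if study.n_countries < 2:
        raise ValueError(
            f"study {study.study_id} has {study.n_countries} countries; "
            "pair extraction requires a multinational study"
        )
    return {CountryPair.of(a, b) for a, b in combinations(sorted(study.countries), 2)}


def build_master_list(studies: Iterable[StudyRecord]) -> MasterList:
    """Pool pair extractions over all studies into one multiset."""
    master = MasterList()
    for study in studies:
        for pair in extract_pairs(study):
            master.add(pair)
    return master


def weight_edges(master: MasterList) -> list[WeightedEdge]:
    """Collapse the master list: one edge per distinct pair, weight = multiplicity."""
    return [
        WeightedEdge(pair, master.counts[pair]) for pair in sorted(master.counts)
    ]


def build_network(studies: Iterable[StudyRecord]) -> TrialNetwork:
    """Assemble the integrated network from multinational studies.

    Node size is the weighted total of connections incident to the country.
    """
    edges = weight_edges(build_master_list(studies))
    nodes: Counter[str] = Counter()
    for edge in edges:
        nodes[edge.pair.u] += edge.weight
        nodes[edge.pair.v] += edge.weight
    return TrialNetwork(nodes=dict(sorted(nodes.items())), edges=edges)


def write_edge_list(net: TrialNetwork, path: str | Path) -> None:
    """CSV edge list (source, target, weight), canonically ordered and sorted."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["source", "target", "weight"])
        for edge in sorted(net.edges, key=lambda e: e.pair):
            writer.writerow([edge.pair.u, edge.pair.v, edge.weight])


def write_gexf(net: TrialNetwork, path: str | Path, region_map: RegionMap | None = None) -> None:
    nx.write_gexf(net.to_networkx(region_map), path)
    # networkx stamps the file with the current date; remove it so repeated
    # runs on identical inputs are byte-identical.
    path = Path(path)
    text = re.sub(r'\s*lastmodifieddate="[^"]*"', "", path.read_text("utf-8"))
    path.write_text(text, "utf-8")


def write_graphml(net: TrialNetwork, path: str | Path, region_map: RegionMap | None = None) -> None:
    nx.write_graphml(net.to_networkx(region_map), path)
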