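"""Seeded synthetic registries with the structure the pipeline assumes.

The generator emulates the gross statistics of a real registry extract:
~89% single-nation studies, multinational studies averaging 6-7 countries,
a heavy-tailed country-popularity distribution with one dominant hub, six
region assignments, a growth-then-plateau year profile peaking in a
configurable year, and a condition distribution dominated by a few labels.

Ground truth (realized pair co-occurrence counts, year counts, condition
counts) is recorded at draw time so pipeline outputs can be checked exactly,
and :func:`expected_edge_weight` provides the analytic expectation of any
pair's edge weight for parameter-recovery tests.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np

from .network_builder import CountryPair
from .registry_io import REGIONS, RegionMap, StudyRecord

logger = logging.getLogger("trialnet.synthetic_data")


@dataclass(frozen=True)
class CountrySpec:
    name: str
    region: str
    popularity: float

    def __post_init__(self) -> None:
        if self.popularity <= 0:
            raise ValueError("popularity must be positive")


def default_universe(
    n_countries: int = 30, hub_factor: float = 10.0
) -> list[CountrySpec]:
    """Thirty synthetic countries over six regions with one 10x hub."""
    specs = []
    for i in range(n_countries):
        region = REGIONS[i % len(REGIONS)]
        pop = hub_factor if i == 0 else 1.0
        specs.append(CountrySpec(f"Country{i:02d}", region, pop))
    return specs


def default_size_distribution(
    mean: float = 6.5, k_min: int = 2, k_max: int = 15
) -> dict[int, float]:
    """Truncated geometric over [k_min, k_max] tuned to the target mean."""
    if not k_min < mean < k_max:
        raise ValueError("target mean must lie strictly inside [k_min, k_max]")
    ks = np.arange(k_min, k_max + 1)

    def mean_at(q: float) -> float:
        w = (1.0 - q) ** (ks - k_min)
        return float((ks * w).sum() / w.sum())

    lo, hi = 1e-9, 1.0 - 1e-9  # q -> 0 gives uniform-ish high mean, q -> 1 gives k_min
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) > mean:
            lo = mid
        else:
            hi = mid
    q = 0.5 * (lo + hi)
    w = (1.0 - q) ** (ks - k_min)
    w /= w.sum()
    return {int(k): float(p) for k, p in zip(ks, w)}


def default_year_profile(
    peak_year: int = 2009,
    start: int = 1990,
    end: int = 2014,
    rise: float = 1.35,
    decline: float = 0.93,
) -> dict[int, float]:
    """Exponential rise to the peak year, then a decline."""
    if rise <= 1.0 or not 0.0 < decline < 1.0:
        raise ValueError("require rise > 1 and 0 < decline < 1")
    weights = {}
    for year in range(start, end + 1):
        if year <= peak_year:
            weights[year] = rise ** (year - peak_year)
        else:
            weights[year] = decline ** (year - peak_year)
    total = sum(weights.values())
    return {y: w / total for y, w in weights.items()}


def default_condition_distribution() -> dict[str, float]:
    probs = {
        "diabetes": 0.25,
        "breast cancer": 0.12,
        "rheumatoid arthritis": 0.10,
        "asthma": 0.08,
        "hiv": 0.07,
        "lung cancer": 0.05,
        "schizophrenia": 0.04,
        "alcoholism": 0.04,
        "malaria": 0.03,
        "leukemia": 0.03,
        "hypertension": 0.19,
    }
    assert abs(sum(probs.values()) - 1.0) < 1e-12
    return probs


@dataclass
class RegistryConfig:
    """Parameters of the synthetic registry generator."""

    n_studies: int = 1000
    p_multinational: float = 0.11
    size_distribution: dict[int, float] = field(
        default_factory=default_size_distribution
    )
    countries: list[CountrySpec] = field(default_factory=default_universe)
    year_profile: dict[int, float] = field(default_factory=default_year_profile)
    condition_distribution: dict[str, float] = field(
        default_factory=default_condition_distribution
    )
    p_second_condition: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_studies < 0:
            raise ValueError("n_studies must be >= 0")
        if not 0.0 <= self.p_multinational <= 1.0:
            raise ValueError("p_multinational must be in [0, 1]")
        for probs, what in (
            (self.size_distribution, "size_distribution"),
            (self.year_profile, "year_profile"),
            (self.condition_distribution, "condition_distribution"),
        ):
            if probs and abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{what} must be normalized")
        if self.size_distribution:
            k_max = max(self.size_distribution)
            if min(self.size_distribution) < 2:
                raise ValueError("multinational study size must be >= 2")
            if k_max > len(self.countries):
                raise ValueError(
                    f"country universe ({len(self.countries)}) smaller than "
                    f"max study size ({k_max})"
                )

    def region_map(self) -> RegionMap:
        return RegionMap({c.name: c.region for c in self.countries})


@dataclass
class GroundTruth:
    """Everything realized during generation, for exact downstream checks."""

    n_studies: int
    n_multinational: int
    pair_counts: Counter = field(default_factory=Counter)
    year_counts: Counter = field(default_factory=Counter)
    condition_counts: Counter = field(default_factory=Counter)
    country_study_counts: Counter = field(default_factory=Counter)


def _sample_without_replacement(
    rng: np.random.Generator, names: list[str], weights: np.ndarray, k: int
) -> list[str]:
    # Sequential popularity-weighted draws with renormalization.
    w = weights.astype(float).copy()
    chosen: list[str] = []
    for _ in range(k):
        p = w / w.sum()
        j = int(rng.choice(len(names), p=p))
        chosen.append(names[j])
        w[j] = 0.0
    return chosen


def generate_registry(
    config: RegistryConfig,
) -> tuple[list[StudyRecord], GroundTruth]:
    """Draw a seeded synthetic registry and its realized ground truth."""
    rng = np.random.default_rng(config.seed)
    names = [c.name for c in config.countries]
    pops = np.array([c.popularity for c in config.countries], dtype=float)

    ks = sorted(config.size_distribution)
    k_probs = np.array([config.size_distribution[k] for k in ks])
    years = sorted(config.year_profile)
    year_probs = np.array([config.year_profile[y] for y in years])
    conds = sorted(config.condition_distribution)
    cond_probs = np.array([config.condition_distribution[c] for c in conds])

    truth = GroundTruth(n_studies=config.n_studies, n_multinational=0)
    records: list[StudyRecord] = []
    for i in range(config.n_studies):
        multinational = rng.random() < config.p_multinational
        if multinational:
            k = ks[int(rng.choice(len(ks), p=k_probs))]
        else:
            k = 1
        countries = _sample_without_replacement(rng, names, pops, k)
        year = years[int(rng.choice(len(years), p=year_probs))] if years else None

        study_conditions = [conds[int(rng.choice(len(conds), p=cond_probs))]]
        if rng.random() < config.p_second_condition:
            extra = conds[int(rng.choice(len(conds), p=cond_probs))]
            if extra not in study_conditions:
                study_conditions.append(extra)

        record = StudyRecord(
            study_id=f"SYN{i:07d}",
            start_year=year,
            countries=frozenset(countries),
            conditions=tuple(study_conditions),
        )
        records.append(record)

        if multinational:
            truth.n_multinational += 1
            if year is not None:
                truth.year_counts[year] += 1
            for country in countries:
                truth.country_study_counts[country] += 1
            for a, b in combinations(sorted(countries), 2):
                truth.pair_counts[CountryPair.of(a, b)] += 1
            for condition in study_conditions:
                truth.condition_counts[condition] += 1
    return records, truth


@dataclass(frozen=True)
class ExpectedEdgeWeight:
    """Expectation of a pair's edge weight, with provenance of the method."""

    value: float
    method: str  # "exact" or "monte_carlo"
    mc_se: float | None = None


def _pair_inclusion_exact(
    pops: dict[str, float], a: str, b: str, k: int
) -> float:
    """P(a and b both drawn in k sequential weighted draws), exactly.

    Dynamic program over (a drawn?, b drawn?, how many removed from each
    class of identically-weighted other countries). Exact because draw
    probabilities depend only on the removed weight mass, not on which
    equally-weighted country was removed.
    """
    w_a, w_b = pops[a], pops[b]
    other = Counter(w for name, w in pops.items() if name not in (a, b))
    classes = sorted(other.items())  # (weight, count) per distinct weight
    states: dict[tuple[bool, bool, tuple[int, ...]], float] = {
        (False, False, tuple(0 for _ in classes)): 1.0
    }
    for _ in range(k):
        nxt: dict[tuple[bool, bool, tuple[int, ...]], float] = Counter()
        for (a_in, b_in, removed), prob in states.items():
            W = (
                (0.0 if a_in else w_a)
                + (0.0 if b_in else w_b)
                + sum(w * (c - r) for (w, c), r in zip(classes, removed))
            )
            if not a_in:
                nxt[(True, b_in, removed)] += prob * w_a / W
            if not b_in:
                nxt[(a_in, True, removed)] += prob * w_b / W
            for j, ((w, c), r) in enumerate(zip(classes, removed)):
                if r < c:
                    new_removed = removed[:j] + (r + 1,) + removed[j + 1 :]
                    nxt[(a_in, b_in, new_removed)] += prob * w * (c - r) / W
        states = dict(nxt)
    return sum(p for (a_in, b_in, _), p in states.items() if a_in and b_in)


def _exact_state_space(pops: dict[str, float], k: int) -> int:
    other = Counter(w for w in pops.values())
    est = 4
    for count in other.values():
        est *= min(count, k) + 1
    return est


def expected_edge_weight(
    config: RegistryConfig,
    a: str,
    b: str,
    *,
    method: str = "auto",
    n_mc: int = 50_000,
    mc_seed: int = 12345,
) -> ExpectedEdgeWeight:
    """Expected co-occurrence count of (a, b) under the sampling scheme.

    E[weight] = n_studies * p_multinational * sum_k P(k) * P(both in draw of k).
    The per-k inclusion probability is computed by an exact dynamic program
    when the state space is small, else by Monte Carlo (se reported).
    """
    names = {c.name for c in config.countries}
    if a == b or a not in names or b not in names:
        raise ValueError("a and b must be distinct countries of the universe")
    pops = {c.name: c.popularity for c in config.countries}
    scale = config.n_studies * config.p_multinational

    if method == "auto":
        method = (
            "exact"
            if _exact_state_space(pops, max(config.size_distribution)) <= 500_000
            else "monte_carlo"
        )
    if method == "exact":
        q = sum(
            p * _pair_inclusion_exact(pops, a, b, k)
            for k, p in config.size_distribution.items()
        )
        return ExpectedEdgeWeight(value=scale * q, method="exact")
    if method != "monte_carlo":
        raise ValueError(f"unknown method {method!r}")

    rng = np.random.default_rng(mc_seed)
    names_list = sorted(pops)
    weights = np.array([pops[n] for n in names_list])
    ks = sorted(config.size_distribution)
    k_probs = np.array([config.size_distribution[k] for k in ks])
    hits = 0
    for _ in range(n_mc):
        k = ks[int(rng.choice(len(ks), p=k_probs))]
        sample = _sample_without_replacement(rng, names_list, weights, k)
        if a in sample and b in sample:
            hits += 1
    q_hat = hits / n_mc
    se = scale * float(np.sqrt(q_hat * (1.0 - q_hat) / n_mc))
    logger.info(
        "expected_edge_weight(%s, %s) by Monte Carlo: q=%.5f (se flagged)", a, b, q_hat
    )
    return ExpectedEdgeWeight(value=scale * q_hat, method="monte_carlo", mc_se=se)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    payload = {
        "n_studies": truth.n_studies,
        "n_multinational": truth.n_multinational,
        "pair_counts": {
            f"{p.u}|{p.v}": c for p, c in sorted(truth.pair_counts.items())
        },
        "year_counts": {str(y): c for y, c in sorted(truth.year_counts.items())},
        "condition_counts": dict(sorted(truth.condition_counts.items())),
        "country_study_counts": dict(sorted(truth.country_study_counts.items())),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
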