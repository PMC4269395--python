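"""Temporal statistics of the annual multinational-study series.

The year axis is contiguous from the earliest to the latest observed start
year, with zero-filled gaps. Year-over-year growth for a year whose
predecessor had zero studies is undefined (None), never coerced to zero.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .registry_io import StudyRecord

logger = logging.getLogger("trialnet.trends")

GROWTH_METHODS = ("mean_yoy", "cagr")


@dataclass
class TrendSeries:
    """Per-year counts of multinational studies and derived statistics."""

    years: list[int] = field(default_factory=list)
    n_studies: list[int] = field(default_factory=list)
    mean_countries: list[float | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.years != sorted(set(self.years)):
            raise ValueError("years must be strictly increasing")
        if not (len(self.years) == len(self.n_studies) == len(self.mean_countries)):
            raise ValueError("year/count/mean arrays must have equal length")

    def __len__(self) -> int:
        return len(self.years)

    def count(self, year: int) -> int:
        return self.n_studies[self.years.index(year)]

    @classmethod
    def from_counts(cls, counts: dict[int, int]) -> "TrendSeries":
        """Convenience constructor for count-only series (tests, simulations)."""
        years = sorted(counts)
        if years:
            years = list(range(years[0], years[-1] + 1))
        n = [counts.get(y, 0) for y in years]
        return cls(years=years, n_studies=n, mean_countries=[None] * len(years))


def studies_per_year(studies: Iterable[StudyRecord]) -> TrendSeries:
    """Count multinational studies by start year on a contiguous year axis.

    Studies with a missing start year are excluded (count logged).
    """
    studies = list(studies)
    dated = [s for s in studies if s.start_year is not None]
    if len(dated) < len(studies):
        logger.info(
            "%d studies without a parseable start year excluded",
            len(studies) - len(dated),
        )
    if not dated:
        return TrendSeries()
    lo = min(s.start_year for s in dated)
    hi = max(s.start_year for s in dated)
    years = list(range(lo, hi + 1))
    buckets: dict[int, list[int]] = {y: [] for y in years}
    for s in dated:
        buckets[s.start_year].append(s.n_countries)
    return TrendSeries(
        years=years,
        n_studies=[len(buckets[y]) for y in years],
        mean_countries=[
            sum(buckets[y]) / len(buckets[y]) if buckets[y] else None for y in years
        ],
    )


def yoy_growth(series: TrendSeries) -> dict[int, float | None]:
    """Year-over-year growth fractions; None where the prior year count is 0."""
    if len(series) < 2:
        raise ValueError("yoy_growth requires a series of at least two years")
    growth: dict[int, float | None] = {}
    for prev, year, n_prev, n in zip(
        series.years, series.years[1:], series.n_studies, series.n_studies[1:]
    ):
        growth[year] = None if n_prev == 0 else (n - n_prev) / n_prev
    return growth


def annualized_growth(
    series: TrendSeries, y0: int, y1: int, method: str = "mean_yoy"
) -> float:
    """Average annual growth over (y0, y1].

    ``mean_yoy`` (default) is the arithmetic mean of the defined
    year-over-year fractions in the window; ``cagr`` is the compound rate
    implied by the endpoint counts alone.
    """
    if method not in GROWTH_METHODS:
        raise ValueError(f"unknown growth method {method!r}")
    if not (y0 < y1):
        raise ValueError("require y0 < y1")
    if y0 not in series.years or y1 not in series.years:
        raise ValueError("window endpoints must lie within the series")
    if method == "cagr":
        n0, n1 = series.count(y0), series.count(y1)
        if n0 == 0:
            raise ValueError("cagr undefined when the base-year count is 0")
        return (n1 / n0) ** (1.0 / (y1 - y0)) - 1.0
    growth = yoy_growth(series)
    window = [g for y, g in growth.items() if y0 < y <= y1 and g is not None]
    if not window:
        raise ValueError("no defined year-over-year fractions in window")
    return sum(window) / len(window)


def peak_year(series: TrendSeries) -> tuple[int, int]:
    """The year with the most studies (earliest year on ties)."""
    if not series.years:
        raise ValueError("peak_year undefined for an empty series")
    best = max(range(len(series)), key=lambda i: (series.n_studies[i], -series.years[i]))
    return series.years[best], series.n_studies[best]


def write_trend_csv(series: TrendSeries, path: str | Path) -> None:
    growth = yoy_growth(series) if len(series) >= 2 else {}
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["year", "n_studies", "mean_countries", "yoy_growth"])
        for i, year in enumerate(series.years):
            mc = series.mean_countries[i]
            g = growth.get(year)
            writer.writerow(
                [
                    year,
                    series.n_studies[i],
                    "" if mc is None else f"{mc:.4f}",
                    "" if g is None else f"{g:.6f}",
                ]
            )


def write_trend_summary_json(
    series: TrendSeries,
    path: str | Path,
    *,
    window: tuple[int, int] | None = None,
    method: str = "mean_yoy",
) -> None:
    summary: dict = {"n_years": len(series)}
    if series.years:
        year, count = peak_year(series)
        summary["peak"] = {"year": year, "n_studies": count}
    if window is not None:
        summary["annualized_growth"] = {
            "window": list(window),
            "method": method,
            "value": annualized_growth(series, *window, method=method),
        }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
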