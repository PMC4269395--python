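"""Reading, normalizing, deduplicating, and classifying registry records.

A registry record is one raw database entry describing a clinical study:
an opaque study id, a start date, a list of participating countries, and a
list of studied conditions. Multiple records may describe the same unique
study; :func:`deduplicate_studies` merges them. Countries are mapped to
canonical names through an alias table and to one of six geographic regions
through a :class:`RegionMap`.
"""

from __future__ import annotations

import csv
import logging
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger("trialnet.registry_io")

#: The six geographic regions every country resolves to.
REGIONS = (
    "North America",
    "South America",
    "Africa",
    "Europe",
    "Asia",
    "Oceania",
)

#: Bucket used in lenient mode for countries absent from the region map.
UNASSIGNED = "Unassigned"

DEFAULT_YEAR_WINDOW = (1900, 2100)

_MONTH_YEAR_RE = re.compile(
    r"^(January|February|March|April|May|June|July|August|September|October"
    r"|November|December)\s+(?:\d{1,2},\s*)?(\d{4})$",
    re.IGNORECASE,
)
_ISO_RE = re.compile(r"^(\d{4})(?:-\d{2}){0,2}$")


class RegistryFormatError(ValueError):
    """Raised for unreadable files or, in strict mode, malformed entries."""


@dataclass(frozen=True)
class StudyRecord:
    """One registered clinical study (or one raw record before dedup).

    ``countries`` is a set of canonical country names, so duplicates and
    aliases are impossible by construction after ingestion. ``start_year``
    is None when the record's start date is missing or unparseable.
    """

    study_id: str
    start_year: int | None
    countries: frozenset[str]
    conditions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.study_id:
            raise ValueError("study_id must be non-empty")
        if not isinstance(self.countries, frozenset):
            object.__setattr__(self, "countries", frozenset(self.countries))
        if not isinstance(self.conditions, tuple):
            object.__setattr__(self, "conditions", tuple(self.conditions))

    @property
    def n_countries(self) -> int:
        return len(self.countries)


class ScopeLabel(Enum):
    """Whether a study was carried out in one country or several.

    Studies with an empty country set are UNLOCATED; they are excluded from
    every downstream analysis.
    """

    SINGLE_NATION = "single_nation"
    MULTINATIONAL = "multinational"
    UNLOCATED = "unlocated"


class AliasTable:
    """Case-insensitive lookup from raw country strings to canonical names.

    Unknown names pass through unchanged (with a warning) so that dirty
    registry dumps degrade gracefully: an unrecognized country is counted
    under its own spelling rather than dropped.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        if mapping:
            for alias, canonical in mapping.items():
                self.add(alias, canonical)

    def add(self, alias: str, canonical: str) -> None:
        self._map[alias.strip().casefold()] = canonical

    def resolve(self, raw: str) -> str | None:
        return self._map.get(raw.strip().casefold())

    def __len__(self) -> int:
        return len(self._map)


@dataclass
class RegionMap:
    """Total function from canonical country names to one of six regions."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r for r in self.mapping.values() if r not in REGIONS}
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    def __contains__(self, country: str) -> bool:
        return country in self.mapping

    def __getitem__(self, country: str) -> str:
        return self.mapping[country]

    def countries(self) -> set[str]:
        return set(self.mapping)

    def regions_present(self) -> set[str]:
        return set(self.mapping.values())


def _load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise RegistryFormatError(f"{path}: expected a key-value mapping")
    return data


def _package_yaml(name: str) -> dict:
    text = resources.files("trialnet.data").joinpath(name).read_text("utf-8")
    return yaml.safe_load(text)


def load_region_map(path: str | Path | None = None) -> RegionMap:
    """Load a region map; the shipped default covers ~200 countries."""
    data = _package_yaml("region_map.yaml") if path is None else _load_yaml(path)
    return RegionMap({str(k): str(v) for k, v in data.items()})


def load_aliases(
    path: str | Path | None = None,
    region_map: RegionMap | None = None,
) -> AliasTable:
    """Load the alias table (shipped default plus optional user overrides).

    Canonical names from the region map are added as identity entries so
    case-variant spellings of canonical names normalize correctly.
    """
    table = AliasTable(_package_yaml("aliases.yaml"))
    if region_map is None:
        region_map = load_region_map()
    for country in region_map.countries():
        if table.resolve(country) is None:
            table.add(country, country)
    if path is not None:
        for alias, canonical in _load_yaml(path).items():
            table.add(str(alias), str(canonical))
    return table


def normalize_country(raw: str, aliases: AliasTable) -> str:
    """Map a raw country string to its canonical name.

    Unknown names pass through unchanged with a warning.
    """
    raw = raw.strip()
    if not raw:
        raise ValueError("empty country name")
    canonical = aliases.resolve(raw)
    if canonical is None:
        logger.warning("unknown country name %r passed through unchanged", raw)
        return raw
    return canonical


def parse_start_year(
    raw: str | None,
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> int | None:
    """Extract a 4-digit start year from a registry date string.

    Accepts "YYYY", "YYYY-MM", "YYYY-MM-DD", "Month YYYY", and
    "Month DD, YYYY". Anything else — or a year outside ``year_window`` —
    yields None.
    """
    if raw is None:
        return None
    raw = raw.strip()
    if not raw:
        return None
    m = _ISO_RE.match(raw) or _MONTH_YEAR_RE.match(raw)
    if m is None:
        return None
    year = int(m.group(m.lastindex))
    lo, hi = year_window
    if not lo <= year <= hi:
        logger.warning("start year %d outside plausibility window [%d, %d]", year, lo, hi)
        return None
    return year


def _split_multi(cell: str | None) -> list[str]:
    if cell is None:
        return []
    return [part.strip() for part in cell.split("|") if part.strip()]


def _make_record(
    study_id: str,
    start_date: str | None,
    raw_countries: list[str],
    raw_conditions: list[str],
    aliases: AliasTable,
    year_window: tuple[int, int],
) -> StudyRecord:
    countries = frozenset(normalize_country(c, aliases) for c in raw_countries)
    if not countries:
        logger.info("record %s has no parseable country list", study_id)
    conditions = tuple(c.strip().casefold() for c in raw_conditions if c.strip())
    return StudyRecord(
        study_id=study_id,
        start_year=parse_start_year(start_date, year_window),
        countries=countries,
        conditions=conditions,
    )


TSV_COLUMNS = ("study_id", "start_date", "countries", "conditions")


def read_registry(
    path: str | Path,
    format: str = "tsv",
    *,
    aliases: AliasTable | None = None,
    strict: bool = False,
    year_window: tuple[int, int] = DEFAULT_YEAR_WINDOW,
) -> list[StudyRecord]:
    """Read raw registry records from a TSV or ClinicalTrials.gov-style XML file.

    One record per input entry; countries and conditions are split, trimmed,
    and normalized. In lenient mode (default) malformed entries are skipped
    with a warning; in strict mode they are fatal.
    """
    path = Path(path)
    if not path.exists():
        raise RegistryFormatError(f"no such file: {path}")
    if aliases is None:
        aliases = load_aliases()
    if format == "tsv":
        return _read_tsv(path, aliases, strict, year_window)
    if format == "ctgov_xml":
        return _read_ctgov_xml(path, aliases, strict, year_window)
    raise ValueError(f"unknown registry format: {format!r}")


def _read_tsv(path, aliases, strict, year_window) -> list[StudyRecord]:
    records: list[StudyRecord] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise RegistryFormatError(f"{path}: empty file, header required")
        missing = set(TSV_COLUMNS) - set(reader.fieldnames)
        if missing:
            raise RegistryFormatError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            study_id = (row.get("study_id") or "").strip()
            if not study_id:
                msg = f"{path}:{lineno}: row without study_id"
                if strict:
                    raise RegistryFormatError(msg)
                logger.warning("%s — skipped", msg)
                continue
            records.append(
                _make_record(
                    study_id,
                    row.get("start_date"),
                    _split_multi(row.get("countries")),
                    _split_multi(row.get("conditions")),
                    aliases,
                    year_window,
                )
            )
    return records


def _read_ctgov_xml(path, aliases, strict, year_window) -> list[StudyRecord]:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise RegistryFormatError(f"{path}: XML parse error: {exc}") from exc
    root = tree.getroot()
    studies = [root] if root.tag == "clinical_study" else list(root.iter("clinical_study"))
    records: list[StudyRecord] = []
    for elem in studies:
        nct = elem.findtext("id_info/nct_id") or elem.findtext("nct_id") or ""
        nct = nct.strip()
        if not nct:
            msg = f"{path}: clinical_study element without an nct_id"
            if strict:
                raise RegistryFormatError(msg)
            logger.warning("%s — skipped", msg)
            continue
        raw_countries = [
            c.text for c in elem.findall("location_countries/country") if c.text
        ]
        raw_conditions = [c.text for c in elem.findall("condition") if c.text]
        records.append(
            _make_record(
                nct,
                elem.findtext("start_date"),
                raw_countries,
                raw_conditions,
                aliases,
                year_window,
            )
        )
    return records


def deduplicate_studies(records: Iterable[StudyRecord]) -> list[StudyRecord]:
    """Merge records sharing a study_id into one record per unique study.

    Countries and conditions are unioned; the earliest non-missing start
    year is kept (conflicts warned). Output is sorted by study_id.
    """
    merged: dict[str, StudyRecord] = {}
    for rec in records:
        prev = merged.get(rec.study_id)
        if prev is None:
            merged[rec.study_id] = rec
            continue
        years = {y for y in (prev.start_year, rec.start_year) if y is not None}
        if len(years) > 1:
            logger.warning(
                "study %s: conflicting start years %s, keeping earliest",
                rec.study_id,
                sorted(years),
            )
        conditions = prev.conditions + tuple(
            c for c in rec.conditions if c not in prev.conditions
        )
        merged[rec.study_id] = replace(
            prev,
            start_year=min(years) if years else None,
            countries=prev.countries | rec.countries,
            conditions=conditions,
        )
    return [merged[sid] for sid in sorted(merged)]


def classify_scope(record: StudyRecord) -> ScopeLabel:
    """Classify a deduplicated study by its distinct-country count."""
    n = record.n_countries
    if n == 0:
        logger.info("study %s is unlocated and will be excluded", record.study_id)
        return ScopeLabel.UNLOCATED
    return ScopeLabel.MULTINATIONAL if n > 1 else ScopeLabel.SINGLE_NATION


def multinational_only(records: Iterable[StudyRecord]) -> list[StudyRecord]:
    """Filter to studies carried out in more than one country."""
    return [r for r in records if classify_scope(r) is ScopeLabel.MULTINATIONAL]


def assign_region(country: str, region_map: RegionMap, *, strict: bool = False) -> str:
    """Resolve a canonical country name to its region.

    Unmapped countries raise in strict mode and fall into the
    ``Unassigned`` bucket (with a warning) in lenient mode.
    """
    if country in region_map:
        return region_map[country]
    if strict:
        raise KeyError(f"country {country!r} not in region map")
    logger.warning("country %r not in region map; bucketed as %s", country, UNASSIGNED)
    return UNASSIGNED


def write_registry_tsv(records: Iterable[StudyRecord], path: str | Path) -> None:
    """Write records in the TSV dialect read by :func:`read_registry`.

    Countries and conditions are sorted so output is deterministic.
    """
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.study_id,
                    "" if rec.start_year is None else str(rec.start_year),
                    "|".join(sorted(rec.countries)),
                    "|".join(rec.conditions),
                ]
            )
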