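import random

import pytest

from trialnet.registry_io import RegionMap, StudyRecord


@pytest.fixture
def study_a() -> StudyRecord:
    """Worked-example study carried out in countries 1, 2, 3."""
    return StudyRecord("A", 2008, frozenset({"1", "2", "3"}))


@pytest.fixture
def study_b() -> StudyRecord:
    """Worked-example study carried out in countries 2, 3, 4."""
    return StudyRecord("B", 2009, frozenset({"2", "3", "4"}))


@pytest.fixture
def worked_example(study_a, study_b) -> list[StudyRecord]:
    return [study_a, study_b]


@pytest.fixture
def two_region_map() -> RegionMap:
    """Countries 1, 2 in Europe; 3, 4 in Asia."""
    return RegionMap({"1": "Europe", "2": "Europe", "3": "Asia", "4": "Asia"})


def random_registry(
    rng: random.Random,
    max_studies: int = 50,
    max_countries: int = 15,
    multinational_only: bool = True,
) -> list[StudyRecord]:
    """Small random multinational registries for oracle comparisons."""
    universe = [f"C{i:02d}" for i in range(rng.randint(2, max_countries))]
    n = rng.randint(0, max_studies)
    studies = []
    for i in range(n):
        k_min = 2 if multinational_only else 1
        k = rng.randint(k_min, max(k_min, min(len(universe), 6)))
        countries = frozenset(rng.sample(universe, k))
        studies.append(StudyRecord(f"S{i:03d}", 2000 + rng.randint(0, 10), countries))
    return studies


def brute_force_edge_weights(studies) -> dict[tuple[str, str], int]:
    """Independent oracle: triple loop over studies x country pairs."""
    weights: dict[tuple[str, str], int] = {}
    for study in studies:
        countries = sorted(study.countries)
        for i in range(len(countries)):
            for j in range(i + 1, len(countries)):
                key = (countries[i], countries[j])
                weights[key] = weights.get(key, 0) + 1
    return weights
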