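"""Reference city metadata from the CAMDA 2020 MetaSUB geolocation challenge.

The MetaSUB main dataset covers 23 cities sampled in 2016 and/or 2017 (28
city-year groups).  For each main-dataset city six ordered categorical
non-microbial traits were derived from climate, location and neighboring-biome
records: summer temperature (3 levels), winter temperature (4), summer
humidity (3), winter humidity (2), a coastal indicator (2) and a binarized
urbanization score (2).  These published tables are small and are bundled
here so that analyses that only need the city-level inputs (group accounting,
trait pattern matching) can run without the sequence-derived data.
"""

from __future__ import annotations

import pandas as pd

TRAIT_COLUMNS = [
    "summer_temperature",
    "winter_temperature",
    "summer_humidity",
    "winter_humidity",
    "coastal",
    "urbanization",
]

#: Number of levels each trait was categorized into.
TRAIT_LEVEL_COUNTS = (3, 4, 3, 2, 2, 2)

#: Collection years per main-dataset city (IATA-style city codes).
MAIN_CITY_YEARS: dict[str, list[int]] = {
    "ARN": [2017],
    "BCN": [2016],
    "BER": [2016],
    "DEN": [2016, 2017],
    "DOH": [2016, 2017],
    "FAI": [2016],
    "HKG": [2017],
    "ICN": [2017],
    "IEV": [2017],
    "ILR": [2016, 2017],
    "KUL": [2017],
    "LCY": [2017],
    "LIS": [2016],
    "NYC": [2016, 2017],
    "OFF": [2016],
    "SAO": [2017],
    "SCL": [2016],
    "SDJ": [2017],
    "SFO": [2017],
    "SGP": [2017],
    "TPE": [2017],
    "TYO": [2016, 2017],
    "ZRH": [2017],
}

CITY_NAMES: dict[str, str] = {
    "ARN": "Stockholm",
    "BCN": "Barcelona",
    "BER": "Berlin",
    "DEN": "Denver",
    "DOH": "Doha",
    "FAI": "Fairbanks",
    "HKG": "Hong Kong",
    "ICN": "Seoul",
    "IEV": "Kiev",
    "ILR": "Ilorin",
    "KUL": "Kuala Lumpur",
    "LCY": "London",
    "LIS": "Lisbon",
    "NYC": "New York",
    "OFF": "Offa",
    "SAO": "Sao Paulo",
    "SCL": "Santiago",
    "SDJ": "Sendai",
    "SFO": "San Francisco",
    "SGP": "Singapore",
    "TPE": "Taipei",
    "TYO": "Tokyo",
    "ZRH": "Zurich",
}

_MAIN_CITY_TRAIT_ROWS = {
    "ARN": (0, 0, 1, 1, 1, 0),
    "BCN": (1, 1, 1, 0, 1, 1),
    "BER": (1, 0, 1, 1, 0, 1),
    "DEN": (1, 0, 0, 0, 0, 0),
    "DOH": (2, 2, 0, 0, 1, 0),
    "FAI": (0, 0, 1, 1, 0, 0),
    "HKG": (2, 2, 2, 1, 1, 0),
    "ICN": (1, 0, 1, 0, 0, 1),
    "IEV": (1, 0, 1, 1, 0, 1),
    "ILR": (2, 3, 2, 0, 0, 0),
    "KUL": (2, 3, 2, 1, 0, 1),
    "LCY": (0, 1, 1, 1, 0, 1),
    "LIS": (1, 1, 1, 1, 1, 0),
    "NYC": (1, 0, 1, 1, 1, 1),
    "OFF": (2, 3, 2, 0, 0, 1),
    "SAO": (1, 2, 1, 1, 0, 1),
    "SCL": (0, 1, 0, 0, 0, 1),
    "SDJ": (1, 0, 2, 1, 1, 1),
    "SFO": (0, 1, 1, 1, 1, 1),
    "SGP": (2, 3, 2, 1, 1, 1),
    "TPE": (2, 2, 1, 1, 1, 1),
    "TYO": (2, 1, 1, 0, 1, 1),
    "ZRH": (0, 0, 1, 1, 1, 1),
}

# Average predicted trait levels for the five mystery cities that were new
# relative to the main dataset (per-sample multi-output MLP predictions,
# averaged within city).
_MYSTERY_AVG_TRAIT_ROWS = {
    "Bogota": (1.417, 0.25, 1.0, 0.917, 0.833, 0.917),
    "Krakow": (1.0, 0.0, 0.909, 0.909, 0.091, 0.909),
    "Marseille": (0.9, 0.2, 1.1, 0.9, 0.4, 0.9),
    "Naples": (1.0, 0.0, 1.0, 1.0, 0.889, 0.889),
    "Vienna": (0.6, 0.0, 1.0, 1.0, 0.4, 0.8),
}

#: Taxa counted over all main-dataset cities, per rank.
MAIN_TAXA_PER_RANK: dict[str, int] = {"order": 193, "family": 288, "species": 1394}


def main_city_traits() -> pd.DataFrame:
    """Trait-level table for the 23 main-dataset cities (city x 6 traits)."""
    df = pd.DataFrame.from_dict(
        _MAIN_CITY_TRAIT_ROWS, orient="index", columns=TRAIT_COLUMNS
    )
    df.index.name = "city"
    return df


def mystery_city_avg_traits() -> pd.DataFrame:
    """Average predicted trait levels for the five new mystery cities."""
    df = pd.DataFrame.from_dict(
        _MYSTERY_AVG_TRAIT_ROWS, orient="index", columns=TRAIT_COLUMNS
    )
    df.index.name = "city"
    return df


def main_city_year_pairs() -> list[tuple[str, int]]:
    """All (city, year) collection pairs of the main dataset, sorted."""
    return [(c, y) for c in sorted(MAIN_CITY_YEARS) for y in MAIN_CITY_YEARS[c]]
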