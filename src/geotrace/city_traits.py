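"""Discretization of continuous city covariates into ordered categorical traits.

Monthly climate records ("month-stat-value" rows per city) are remapped to
meteorological seasons — hemisphere-aware, so that e.g. July is winter for a
southern-hemisphere city — and seasonal means feed a k-means discretization
whose labels are re-ordered by ascending cluster mean (a higher label always
means a higher value).  A coastal indicator passes through unchanged, and the
three neighboring Anthromes biomes are converted to an urbanization score
(wildlands 0 ... dense settlements 5, summed over the three biomes) which is
binarized at the median across cities.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

TRAIT_COLUMNS = [
    "summer_temperature",
    "winter_temperature",
    "summer_humidity",
    "winter_humidity",
    "coastal",
    "urbanization",
]

BIOME_SCORES = {
    "wildlands": 0,
    "forested": 1,
    "rangelands": 2,
    "croplands": 3,
    "villages": 4,
    "dense settlements": 5,
}

_N_SEASONS = {
    "winter": (12, 1, 2),
    "spring": (3, 4, 5),
    "summer": (6, 7, 8),
    "autumn": (9, 10, 11),
}
_OPPOSITE = {"winter": "summer", "summer": "winter",
             "spring": "autumn", "autumn": "spring"}


def month_to_season(month: int, hemisphere: str) -> str:
    """Meteorological season of a calendar month (Dec-Feb = northern winter)."""
    if month not in range(1, 13):
        raise ValueError(f"invalid month {month!r}")
    if hemisphere not in {"N", "S"}:
        raise ValueError(f"hemisphere must be 'N' or 'S', got {hemisphere!r}")
    for season, months in _N_SEASONS.items():
        if month in months:
            return season if hemisphere == "N" else _OPPOSITE[season]
    raise AssertionError("unreachable")


def choose_k(values: Iterable[float], k_range: tuple[int, int] = (2, 4),
             seed: int = 0, margin: float = 0.02) -> int:
    """Cluster count maximizing the mean silhouette over ``k_range``.

    A parsimony rule breaks near-ties: a larger k is preferred only when it
    improves the silhouette by more than ``margin`` (absolute, on the [-1, 1]
    silhouette scale), which guards against splitting a tight cluster of few
    cities on a hair-thin gain.
    With fewer distinct values than ``k_range[0]`` the number of distinct
    values is returned (a constant vector gives k=1).
    """
    x = np.asarray(list(values), dtype=float).reshape(-1, 1)
    n_distinct = len(np.unique(x))
    k_min, k_max = k_range
    if n_distinct < max(2, k_min):
        return n_distinct
    best_k, best_score = k_min, -np.inf
    for k in range(k_min, min(k_max, n_distinct, len(x) - 1) + 1):
        labels = kmeans_discretize(x.ravel(), k, seed=seed)
        score = silhouette_score(x, labels)
        if score > best_score + margin:
            best_k, best_score = k, score
    return best_k


def kmeans_discretize(values: Iterable[float], k: int, seed: int = 0) -> np.ndarray:
    """k-means labels relabeled by ascending cluster mean (ordinal 0..k-1)."""
    x = np.asarray(list(values), dtype=float).reshape(-1, 1)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(np.unique(x)):
        raise ValueError(f"k={k} exceeds the {len(np.unique(x))} distinct values")
    if k == 1:
        return np.zeros(len(x), dtype=int)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(x)
    order = np.argsort(km.cluster_centers_.ravel())
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[km.labels_]


def urbanization_score(biomes: tuple[str, str, str]) -> int:
    """Sum of the three neighboring-biome scores (0-15)."""
    if len(biomes) != 3:
        raise ValueError("exactly three neighboring biomes required")
    try:
        return sum(BIOME_SCORES[b] for b in biomes)
    except KeyError as exc:
        raise ValueError(f"unknown biome label {exc.args[0]!r}") from None


def binarize_urbanization(scores: Mapping[str, int]) -> dict[str, int]:
    """1 for cities at or above the median urbanization score, else 0."""
    if len(scores) < 2:
        raise ValueError("need scores for at least 2 cities")
    med = float(np.median(list(scores.values())))
    return {c: int(v >= med) for c, v in scores.items()}


def combination_count(level_counts: Iterable[int]) -> int:
    """Maximum number of distinct trait-level combinations."""
    counts = list(level_counts)
    if any(c < 1 for c in counts):
        raise ValueError("level counts must be >= 1")
    return math.prod(counts)


def seasonal_means(climate: pd.DataFrame, stat: str) -> pd.DataFrame:
    """Per-city seasonal means of a monthly stat, hemisphere-aware.

    ``climate`` is a long table with columns city, month, stat, value,
    hemisphere (repeated per row).  Returns a city x season frame.
    """
    sub = climate[climate["stat"] == stat]
    if sub.empty:
        raise ValueError(f"no rows for stat {stat!r}")
    sub = sub.assign(
        season=[month_to_season(int(m), h)
                for m, h in zip(sub["month"], sub["hemisphere"])]
    )
    return sub.pivot_table(index="city", columns="season", values="value",
                           aggfunc="mean")


def discretize_city_traits(
    climate: pd.DataFrame,
    attributes: pd.DataFrame,
    k_overrides: Mapping[str, int] | None = None,
    k_range: tuple[int, int] = (2, 4),
    seed: int = 0,
) -> pd.DataFrame:
    """Build the six-trait ordinal profile table (city x traits).

    ``climate``: long monthly table (city, month, stat, value, hemisphere).
    ``attributes``: per-city frame indexed by city with columns ``coastal``
    and ``biome_1``/``biome_2``/``biome_3``.
    """
    k_overrides = dict(k_overrides or {})
    temp = seasonal_means(climate, "temperature_mean")
    hum = seasonal_means(climate, "humidity_mean")
    cities = list(temp.index)

    feature_values = {
        "summer_temperature": temp["summer"],
        "winter_temperature": temp["winter"],
        "summer_humidity": hum["summer"],
        "winter_humidity": hum["winter"],
    }
    out = pd.DataFrame(index=pd.Index(cities, name="city"))
    for trait, vals in feature_values.items():
        vals = vals.loc[cities]
        k = k_overrides.get(trait) or choose_k(vals, k_range=k_range, seed=seed)
        out[trait] = kmeans_discretize(vals, k, seed=seed)

    attrs = attributes.loc[cities]
    out["coastal"] = attrs["coastal"].astype(int)
    scores = {
        c: urbanization_score(
            (attrs.at[c, "biome_1"], attrs.at[c, "biome_2"], attrs.at[c, "biome_3"])
        )
        for c in cities
    }
    binary = binarize_urbanization(scores)
    out["urbanization"] = [binary[c] for c in cities]
    return out[TRAIT_COLUMNS]
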