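"""Synthetic OTU count tables, metadata and city covariates with planted structure.

The generator emulates the statistical features of a multi-city urban
microbiome study that the downstream pipeline relies on:

* city-specific *signature taxa*: each city's planted taxa get an additive
  shift on the log-abundance scale before a softmax converts log-abundances
  to per-sample taxon proportions;
* year-to-year batch shifts within a city (per-taxon Gaussian shifts shared
  by all samples of a city-year group);
* log-normal library-size variation plus a minority of planted extreme
  low-depth samples (depth scaled by a factor well below the 20%-of-median
  cutoff so the depth filter can be exercised);
* counts drawn multinomially given proportions and library size;
* monthly climate series, a coastal flag and neighboring-biome labels whose
  discretization provably recovers the planted city trait levels.

Everything is deterministic given the config seed.  Ground truth (signature
taxa, planted outliers, trait levels, unseen "mystery" cities) is returned
alongside the tables for recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import reference
from .city_traits import TRAIT_COLUMNS
from .data_io import OtuTable, attach_group_labels, group_label

logger = logging.getLogger(__name__)

# planted level cardinalities per trait (summer/winter temperature,
# summer/winter humidity, coastal, urbanization)
_TRAIT_CARDINALITIES = dict(zip(TRAIT_COLUMNS, reference.TRAIT_LEVEL_COUNTS))

_LOW_BIOMES = ("wildlands", "forested", "rangelands")
_HIGH_BIOMES = ("croplands", "villages", "dense settlements")


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults mirror the scale of the MetaSUB CAMDA 2020 main dataset:
    23 cities with 28 city-year groups, taxa counted at the order, family and
    species ranks, library sizes log-normal around a median of 1e5 reads, and
    ~6.5% of samples planted as extreme low-depth outliers.
    """

    years_per_city: dict[str, list[int]] = field(
        default_factory=lambda: {c: list(y) for c, y in
                                 reference.MAIN_CITY_YEARS.items()})
    samples_per_group: int = 35
    n_taxa_per_rank: dict[str, int] = field(
        default_factory=lambda: dict(reference.MAIN_TAXA_PER_RANK))
    n_signature_taxa_per_city: int = 10
    signature_effect: float = 1.0  # log-scale abundance shift of planted taxa
    batch_effect_sd: float = 0.3  # per-year, per-taxon log-scale shift
    library_size_mean: float = 1e5  # median of the log-normal library size
    library_size_dispersion: float = 0.6  # sd of log library size
    outlier_fraction: float = 0.065
    outlier_depth_factor: float = 0.05  # must stay below the 0.2 depth cutoff
    baseline_log_sd: float = 1.5  # spread of baseline log-abundances
    sample_noise_sd: float = 0.5  # within-city per-sample log-scale variation
    n_mystery_unseen: int = 0  # cities absent from the main tables
    n_mystery_seen: int = 0  # main cities re-sampled into the mystery tables
    mystery_samples_per_city: int = 15
    seed: int = 0

    @property
    def n_cities(self) -> int:
        return len(self.years_per_city)

    @property
    def n_taxa(self) -> int:
        return sum(self.n_taxa_per_rank.values())

    def validate(self) -> None:
        if self.samples_per_group < 5:
            raise ValueError("samples_per_group must be >= 5")
        total_sig = (self.n_cities + self.n_mystery_unseen) \
            * self.n_signature_taxa_per_city
        if self.n_signature_taxa_per_city > self.n_taxa or total_sig > self.n_taxa:
            raise ValueError("not enough taxa for the requested signature sets")
        if not 0 <= self.outlier_fraction < 1:
            raise ValueError("outlier_fraction must be in [0, 1)")
        if not 0 < self.outlier_depth_factor < 0.2:
            raise ValueError(
                "outlier_depth_factor must be in (0, 0.2) so planted outliers "
                "fall below the depth cutoff")
        if self.signature_effect < 0 or self.batch_effect_sd < 0:
            raise ValueError("effects must be non-negative")
        if min(self.library_size_mean, self.library_size_dispersion) <= 0:
            raise ValueError("library size parameters must be positive")
        if self.n_mystery_seen > self.n_cities:
            raise ValueError("n_mystery_seen exceeds the number of cities")


@dataclass
class SimTruth:
    """Ground truth of a simulated study."""

    signature_taxa: dict[str, set[str]]
    outlier_samples: set[str]
    city_trait_levels: dict[str, dict[str, int]]
    mystery_cities: set[str]
    hemisphere: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_taxa": {c: sorted(v) for c, v in self.signature_taxa.items()},
            "outlier_samples": sorted(self.outlier_samples),
            "city_trait_levels": self.city_trait_levels,
            "mystery_cities": sorted(self.mystery_cities),
            "hemisphere": self.hemisphere,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class SimulatedStudy:
    counts: OtuTable
    meta: pd.DataFrame
    truth: SimTruth
    mystery_counts: OtuTable | None = None
    mystery_meta: pd.DataFrame | None = None


def small_config(
    n_cities: int = 5,
    samples_per_group: int = 12,
    multi_year_cities: int = 0,
    n_taxa_per_rank: dict[str, int] | None = None,
    **kwargs,
) -> SimConfig:
    """A reduced study design for fast experiments: cities C01..Cnn."""
    years = {}
    for i in range(n_cities):
        city = f"C{i + 1:02d}"
        years[city] = [2016, 2017] if i < multi_year_cities else [2017]
    return SimConfig(
        years_per_city=years,
        samples_per_group=samples_per_group,
        n_taxa_per_rank=n_taxa_per_rank
        or {"order": 40, "family": 60, "species": 100},
        library_size_mean=2e4,
        **kwargs,
    )


def _taxon_ids(config: SimConfig, rng: np.random.Generator) -> list[str]:
    ids: list[str] = []
    for rank, prefix in (("order", "o__"), ("family", "f__"), ("species", "s__")):
        n = config.n_taxa_per_rank.get(rank, 0)
        for i in range(n):
            if rank == "species" and i % 5 == 4:
                # species resolved only to genus level are written Genus.spp
                ids.append(f"{prefix}Genus{i:04d}.spp")
            else:
                ids.append(f"{prefix}{rank.capitalize()}{i:04d}")
    return ids


def _plant_trait_levels(cities: list[str], rng: np.random.Generator
                        ) -> dict[str, dict[str, int]]:
    """Cycle each trait's levels over a shuffled city order.

    Levels are balanced across cities; for the binary urbanization trait the
    cycle starts at 1 so at least half of the cities are planted high, which
    guarantees the >=-median binarization recovers the planted levels.
    """
    n = len(cities)
    levels: dict[str, dict[str, int]] = {c: {} for c in cities}
    for trait, card in _TRAIT_CARDINALITIES.items():
        card = min(card, n)
        order = list(rng.permutation(cities))
        if trait == "urbanization":
            cycle = [1, 0]
        else:
            cycle = list(range(card))
        for i, c in enumerate(order):
            levels[c][trait] = cycle[i % len(cycle)]
    return levels


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate the full synthetic study (main tables, truth, optional mystery)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    taxa = _taxon_ids(config, rng)
    n_taxa = len(taxa)
    baseline = rng.normal(0.0, config.baseline_log_sd, n_taxa)

    main_cities = sorted(config.years_per_city)
    unseen = [f"MY{i + 1:02d}" for i in range(config.n_mystery_unseen)]
    all_cities = main_cities + unseen

    sig_pool = rng.permutation(n_taxa)
    signature_taxa: dict[str, set[str]] = {}
    sig_shift: dict[str, np.ndarray] = {}
    k = config.n_signature_taxa_per_city
    for i, city in enumerate(all_cities):
        idx = sig_pool[i * k:(i + 1) * k]
        signature_taxa[city] = {taxa[j] for j in idx}
        shift = np.zeros(n_taxa)
        shift[idx] = config.signature_effect
        sig_shift[city] = shift

    hemisphere = {
        c: ("S" if rng.random() < 0.25 else "N") for c in main_cities
    }
    trait_levels = _plant_trait_levels(main_cities, rng)

    def _group_samples(city: str, year: int, n: int, tag: str
                       ) -> tuple[list[str], np.ndarray, np.ndarray]:
        batch = rng.normal(0.0, config.batch_effect_sd, n_taxa) \
            if config.batch_effect_sd > 0 else np.zeros(n_taxa)
        logits = baseline + sig_shift[city] + batch
        noise = rng.normal(0.0, config.sample_noise_sd, (n, n_taxa)) \
            if config.sample_noise_sd > 0 else np.zeros((n, n_taxa))
        logits = logits + noise  # per-sample within-city variation
        props = np.exp(logits - logits.max(axis=1, keepdims=True))
        props /= props.sum(axis=1, keepdims=True)
        libs = rng.lognormal(np.log(config.library_size_mean),
                             config.library_size_dispersion, n)
        ids = [f"{tag}{group_label(city, year)}.{j + 1:03d}" for j in range(n)]
        return ids, props, libs

    # ----- main tables -------------------------------------------------
    sample_ids: list[str] = []
    rows_meta = []
    prop_list, lib_list = [], []
    for city in main_cities:
        for year in sorted(config.years_per_city[city]):
            ids, props, libs = _group_samples(
                city, year, config.samples_per_group, "")
            sample_ids.extend(ids)
            rows_meta.extend({"sample_id": s, "city": city, "year": year}
                             for s in ids)
            prop_list.extend(list(props))
            lib_list.append(libs)
    libs = np.concatenate(lib_list)

    n_samples = len(sample_ids)
    n_out = int(round(config.outlier_fraction * n_samples))
    out_idx = rng.choice(n_samples, size=n_out, replace=False) if n_out else []
    libs = libs.copy()
    for i in out_idx:
        libs[i] *= config.outlier_depth_factor
    libs = np.maximum(np.round(libs).astype(np.int64), 50)

    counts = np.vstack([
        rng.multinomial(libs[i], prop_list[i]) for i in range(n_samples)
    ])
    table = OtuTable(sample_ids, taxa, counts)
    meta = attach_group_labels(pd.DataFrame(rows_meta))

    truth = SimTruth(
        signature_taxa=signature_taxa,
        outlier_samples={sample_ids[i] for i in out_idx},
        city_trait_levels=trait_levels,
        mystery_cities=set(unseen),
        hemisphere=hemisphere,
    )
    _verify_signatures(table, meta, truth, config)

    # ----- mystery tables ----------------------------------------------
    mystery_counts = mystery_meta = None
    if config.n_mystery_unseen or config.n_mystery_seen:
        m_ids: list[str] = []
        m_rows, m_props, m_libs = [], [], []
        seen = main_cities[:config.n_mystery_seen]
        for city in seen + unseen:
            year = 2017
            ids, props, libs_g = _group_samples(
                city, year, config.mystery_samples_per_city, "MYS.")
            m_ids.extend(ids)
            m_rows.extend({"sample_id": s, "city": city, "year": year}
                          for s in ids)
            m_props.extend(list(props))
            m_libs.append(libs_g)
        mlibs = np.maximum(
            np.round(np.concatenate(m_libs)).astype(np.int64), 50)
        m_counts = np.vstack([
            rng.multinomial(mlibs[i], m_props[i]) for i in range(len(m_ids))
        ])
        mystery_counts = OtuTable(m_ids, taxa, m_counts)
        mystery_meta = attach_group_labels(pd.DataFrame(m_rows))

    return SimulatedStudy(table, meta, truth, mystery_counts, mystery_meta)


def generate_counts(config: SimConfig) -> tuple[OtuTable, pd.DataFrame, SimTruth]:
    """Main-dataset triple (counts, metadata, truth); see ``simulate_study``."""
    study = simulate_study(config)
    return study.counts, study.meta, study.truth


def _verify_signatures(table: OtuTable, meta: pd.DataFrame, truth: SimTruth,
                       config: SimConfig) -> None:
    """Empirically check planted taxa are enriched in their own city."""
    if config.signature_effect <= 0:
        return
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    city = meta.set_index("sample_id").loc[table.sample_ids, "city"].to_numpy()
    tpos = {t: j for j, t in enumerate(table.taxon_ids)}
    for c, taxa_c in truth.signature_taxa.items():
        if c in truth.mystery_cities:
            continue
        mask = city == c
        for t in taxa_c:
            j = tpos[t]
            if rel[mask, j].mean() <= rel[~mask, j].mean():
                logger.warning(
                    "planted signature taxon %s not empirically enriched in %s "
                    "(weak effect relative to sampling noise)", t, c,
                )


# --------------------------------------------------------------- city traits

# seasonal anchor (base) and per-level gap for each climate trait; gaps are
# large relative to the ~1-unit within-level noise so k-means separates levels
_CLIMATE_PLAN = {
    "summer_temperature": ("temperature", "summer", 14.0, 8.0),
    "winter_temperature": ("temperature", "winter", -6.0, 8.0),
    "summer_humidity": ("humidity", "summer", 35.0, 15.0),
    "winter_humidity": ("humidity", "winter", 40.0, 20.0),
}


def generate_city_traits(
    config: SimConfig, truth: SimTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monthly climate rows plus per-city attributes matching planted levels.

    Returns ``(climate, attributes)``: a long frame (city, month, stat, value,
    hemisphere) covering temperature/humidity min/mean/max for all 12 months,
    and a per-city frame (coastal, biome_1..3, hemisphere) indexed by city.
    """
    if not truth.city_trait_levels:
        raise ValueError("truth.city_trait_levels is empty")
    rng = np.random.default_rng(config.seed + 7)
    from .city_traits import month_to_season  # local to avoid cycle at import

    climate_rows = []
    attr_rows = {}
    for city, levels in truth.city_trait_levels.items():
        hemi = truth.hemisphere.get(city, "N")
        seasonal: dict[tuple[str, str], float] = {}
        for trait, (var, season, base, gap) in _CLIMATE_PLAN.items():
            seasonal[(var, season)] = (
                base + gap * levels[trait] + rng.normal(0, 0.8)
            )
        for var in ("temperature", "humidity"):
            summer = seasonal[(var, "summer")]
            winter = seasonal[(var, "winter")]
            mid = (summer + winter) / 2
            by_season = {"summer": summer, "winter": winter,
                         "spring": mid, "autumn": mid}
            for month in range(1, 13):
                season = month_to_season(month, hemi)
                mean = by_season[season] + rng.normal(0, 0.5)
                spread = abs(rng.normal(5, 0.5))
                for stat, value in ((f"{var}_mean", mean),
                                    (f"{var}_min", mean - spread),
                                    (f"{var}_max", mean + spread)):
                    climate_rows.append(
                        {"city": city, "month": month, "stat": stat,
                         "value": round(float(value), 3), "hemisphere": hemi})
        if levels["urbanization"] == 1:
            biomes = rng.choice(_HIGH_BIOMES, size=3, replace=True)
        else:
            biomes = rng.choice(_LOW_BIOMES, size=3, replace=True)
        attr_rows[city] = {
            "coastal": levels["coastal"],
            "biome_1": biomes[0], "biome_2": biomes[1], "biome_3": biomes[2],
            "hemisphere": hemi,
        }

    climate = pd.DataFrame(climate_rows)
    attributes = pd.DataFrame.from_dict(attr_rows, orient="index")
    attributes.index.name = "city"
    return climate, attributes


def planted_profiles(truth: SimTruth) -> pd.DataFrame:
    """Planted trait levels as a city x traits frame (main cities only)."""
    df = pd.DataFrame.from_dict(truth.city_trait_levels, orient="index")
    df.index.name = "city"
    return df[TRAIT_COLUMNS].astype(int)


def write_study(study: SimulatedStudy, out_dir: str | Path) -> None:
    """Write all tables of a simulated study as TSV/JSON under ``out_dir``."""
    from .data_io import write_counts, write_metadata

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_counts(study.counts, out / "counts.tsv")
    write_metadata(study.meta, out / "metadata.tsv")
    study.truth.to_json(out / "truth.json")
    if study.mystery_counts is not None:
        write_counts(study.mystery_counts, out / "mystery_counts.tsv")
        write_metadata(study.mystery_meta, out / "mystery_metadata.tsv")
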