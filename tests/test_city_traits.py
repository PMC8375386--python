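import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geotrace import binarize_urbanization, choose_k, combination_count, \
    kmeans_discretize, month_to_season, urbanization_score
from geotrace.city_traits import BIOME_SCORES, discretize_city_traits
from geotrace.synthetic import generate_city_traits, planted_profiles, \
    simulate_study, small_config


@pytest.mark.parametrize(
    "month, hemisphere, season",
    [
        (7, "N", "summer"),
        (7, "S", "winter"),
        (1, "S", "summer"),
        (12, "N", "winter"),
        (4, "N", "spring"),
        (10, "S", "spring"),
    ],
)
def test_month_to_season_is_hemisphere_aware(month, hemisphere, season):
    assert month_to_season(month, hemisphere) == season


def test_month_to_season_rejects_bad_input():
    with pytest.raises(ValueError):
        month_to_season(13, "N")
    with pytest.raises(ValueError):
        month_to_season(5, "X")


def test_choose_k_finds_two_separated_clouds():
    rng = np.random.default_rng(0)
    values = np.concatenate([rng.normal(0, 0.3, 10), rng.normal(10, 0.3, 10)])
    assert choose_k(values, k_range=(2, 5), seed=0) == 2


def test_choose_k_degenerate_vectors():
    assert choose_k([3.0] * 6) == 1
    assert choose_k([1.0, 1.0, 2.0, 2.0, 2.0]) == 2


def test_kmeans_labels_are_value_ordered():
    labels = kmeans_discretize([1, 1, 1, 10, 10, 10], k=2, seed=0)
    assert list(labels) == [0, 0, 0, 1, 1, 1]
    values = np.array([5.0, -2.0, 14.0, -1.5, 5.5, 13.0, 4.8])
    labels = kmeans_discretize(values, k=3, seed=0)
    means = [values[labels == j].mean() for j in range(3)]
    assert means == sorted(means)


def test_kmeans_degenerate_inputs():
    assert list(kmeans_discretize([7.0, 7.0, 7.0], k=1)) == [0, 0, 0]
    with pytest.raises(ValueError, match="distinct"):
        kmeans_discretize([1.0, 1.0, 2.0], k=3)


@pytest.mark.parametrize(
    "biomes, score",
    [
        (("wildlands",) * 3, 0),
        (("dense settlements",) * 3, 15),
        (("croplands", "villages", "rangelands"), 9),
    ],
)
def test_urbanization_score_sums(biomes, score):
    assert urbanization_score(biomes) == score


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.permutations(sorted(BIOME_SCORES)))
def test_urbanization_score_is_permutation_invariant(perm):
    triple = tuple(perm[:3])
    for rolled in (triple, triple[::-1], triple[1:] + triple[:1]):
        assert urbanization_score(rolled) == urbanization_score(triple)


def test_urbanization_rejects_unknown_biome():
    with pytest.raises(ValueError, match="unknown biome"):
        urbanization_score(("wildlands", "sea", "villages"))


def test_binarize_urbanization_median_rule():
    assert binarize_urbanization({"A": 3, "B": 9, "C": 15}) == \
        {"A": 0, "B": 1, "C": 1}
    assert binarize_urbanization({"A": 5, "B": 5}) == {"A": 1, "B": 1}
    base = {"A": 1, "B": 4, "C": 9, "D": 12}
    shifted = {c: v + 7 for c, v in base.items()}
    assert binarize_urbanization(base) == binarize_urbanization(shifted)


@pytest.mark.parametrize(
    "cards, count",
    [((3, 4, 3, 2, 2, 2), 288), ((1, 1, 1, 1, 1, 1), 1), ((2, 3), 6)],
)
def test_combination_count(cards, count):
    assert combination_count(cards) == count


@pytest.fixture(scope="module")
def trait_world():
    # 12 cities so every planted level of the 4-level trait has >= 3 cities
    cfg = small_config(n_cities=12, samples_per_group=5, seed=5)
    study = simulate_study(cfg)
    climate, attributes = generate_city_traits(cfg, study.truth)
    return cfg, study, climate, attributes


def test_southern_hemisphere_summer_is_dec_feb(trait_world):
    _, study, climate, _ = trait_world
    south = [c for c, h in study.truth.hemisphere.items() if h == "S"]
    if not south:
        pytest.skip("no southern city drawn in this configuration")
    city = south[0]
    rows = climate[(climate["city"] == city)
                   & (climate["stat"] == "temperature_mean")]
    monthly = rows.set_index("month")["value"]
    djf = monthly.loc[[12, 1, 2]].mean()
    jja = monthly.loc[[6, 7, 8]].mean()
    level = study.truth.city_trait_levels[city]
    # Dec-Feb carries this city's *summer* values
    expected_summer = 14.0 + 8.0 * level["summer_temperature"]
    expected_winter = -6.0 + 8.0 * level["winter_temperature"]
    assert abs(djf - expected_summer) < 4.0
    assert abs(jja - expected_winter) < 4.0


def test_discretization_recovers_planted_levels(trait_world):
    cfg, study, climate, attributes = trait_world
    profiles = discretize_city_traits(climate, attributes, seed=0)
    planted = planted_profiles(study.truth).loc[profiles.index]
    assert profiles.equals(planted)


def test_urbanization_binarization_matches_plant(trait_world):
    _, study, _, attributes = trait_world
    scores = {
        c: urbanization_score(tuple(attributes.loc[c, ["biome_1", "biome_2",
                                                       "biome_3"]]))
        for c in attributes.index
    }
    binary = binarize_urbanization(scores)
    for c, levels in study.truth.city_trait_levels.items():
        assert binary[c] == levels["urbanization"]
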