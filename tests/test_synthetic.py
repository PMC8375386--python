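import numpy as np
import pandas as pd
import pytest

from geotrace import build_group_index, log2_cpm, order_sum_filter
from geotrace.synthetic import SimConfig, generate_counts, simulate_study, \
    small_config


def test_same_seed_gives_bit_identical_tables():
    cfg = small_config(n_cities=4, samples_per_group=6, n_mystery_unseen=1,
                       seed=9)
    a, b = simulate_study(cfg), simulate_study(cfg)
    assert np.array_equal(a.counts.counts, b.counts.counts)
    assert a.counts.sample_ids == b.counts.sample_ids
    assert a.meta.equals(b.meta)
    assert np.array_equal(a.mystery_counts.counts, b.mystery_counts.counts)
    assert a.truth.signature_taxa == b.truth.signature_taxa
    assert a.truth.outlier_samples == b.truth.outlier_samples


def test_planted_outliers_are_the_filtered_samples():
    cfg = small_config(n_cities=4, samples_per_group=12,
                       outlier_fraction=0.08, outlier_depth_factor=0.05,
                       library_size_dispersion=0.3, seed=3)
    table, meta, truth = generate_counts(cfg)
    index = build_group_index(meta)
    assert truth.outlier_samples <= set(table.sample_ids)
    _, report = order_sum_filter(table, index)
    assert set(report.removed) == truth.outlier_samples


def test_no_outliers_planted_means_none_removed():
    cfg = small_config(n_cities=4, samples_per_group=12, outlier_fraction=0.0,
                       library_size_dispersion=0.3, seed=4)
    table, meta, truth = generate_counts(cfg)
    assert truth.outlier_samples == set()
    _, report = order_sum_filter(table, build_group_index(meta))
    assert report.removed == []


def test_signature_taxa_are_enriched_in_their_city(strong_study):
    s = strong_study
    table, truth = s.study.counts, s.study.truth
    rel = table.counts / table.counts.sum(axis=1, keepdims=True)
    city = s.study.meta.set_index("sample_id").loc[table.sample_ids, "city"]
    pos = {t: j for j, t in enumerate(table.taxon_ids)}
    for c in sorted(s.cfg.years_per_city):
        mask = (city == c).to_numpy()
        for t in truth.signature_taxa[c]:
            j = pos[t]
            assert rel[mask, j].mean() > rel[~mask, j].mean()


def test_group_centroids_separate_under_strong_signal(strong_study):
    s = strong_study
    X = s.X.to_numpy()
    labels = s.index.labels_for(list(s.X.index)).to_numpy()
    centroids = {g: X[labels == g].mean(axis=0) for g in s.index.groups}
    within = np.mean([
        np.linalg.norm(X[labels == g] - centroids[g], axis=1).mean()
        for g in s.index.groups
    ])
    between = np.mean([
        np.linalg.norm(centroids[g1] - centroids[g2])
        for g1 in s.index.groups for g2 in s.index.groups if g1 < g2
    ])
    assert between > within


def test_mystery_cities_disjoint_from_main(strong_study):
    truth = strong_study.study.truth
    assert truth.mystery_cities.isdisjoint(strong_study.cfg.years_per_city)
    mys_cities = set(strong_study.study.mystery_meta["city"])
    assert truth.mystery_cities <= mys_cities


def test_invalid_configs_are_rejected():
    with pytest.raises(ValueError, match="samples_per_group"):
        small_config(samples_per_group=3).validate()
    with pytest.raises(ValueError, match="outlier_depth_factor"):
        small_config(outlier_depth_factor=0.3).validate()
    with pytest.raises(ValueError, match="signature"):
        small_config(n_signature_taxa_per_city=10**6).validate()


def test_default_config_mirrors_study_design():
    cfg = SimConfig()
    assert cfg.n_cities == 23
    assert sum(len(v) for v in cfg.years_per_city.values()) == 28
    assert cfg.n_taxa == 193 + 288 + 1394


def test_taxon_ids_are_rank_prefixed_with_genus_spp_species():
    cfg = small_config(n_cities=4, samples_per_group=5, seed=0)
    table, _, _ = generate_counts(cfg)
    assert len(table.taxa_at_rank("order")) == 40
    assert len(table.taxa_at_rank("family")) == 60
    assert len(table.taxa_at_rank("species")) == 100
    assert any(t.endswith(".spp") for t in table.taxa_at_rank("species"))
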