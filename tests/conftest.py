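from types import SimpleNamespace

import pytest

from geotrace import build_group_index, log2_cpm, ubiquity_filter
from geotrace.synthetic import simulate_study, small_config


def _prepare(cfg):
    study = simulate_study(cfg)
    index = build_group_index(study.meta)
    keep = ubiquity_filter(study.counts)
    taxa = [t for t in study.counts.taxon_ids if t in keep]
    X = log2_cpm(study.counts.subset_taxa(taxa))
    mystery_X = None
    if study.mystery_counts is not None:
        mystery_X = log2_cpm(study.mystery_counts.subset_taxa(taxa))
    return SimpleNamespace(cfg=cfg, study=study, index=index, X=X,
                           mystery_X=mystery_X)


@pytest.fixture(scope="session")
def strong_study():
    """Five cities with strong, clean signatures plus two unseen cities."""
    cfg = small_config(
        n_cities=5, samples_per_group=12, signature_effect=2.0,
        batch_effect_sd=0.0, outlier_fraction=0.0,
        n_mystery_unseen=2, mystery_samples_per_city=15, seed=21,
    )
    return _prepare(cfg)


@pytest.fixture(scope="session")
def null_study():
    """Five exchangeable cities: no signature, no batch shifts."""
    cfg = small_config(
        n_cities=5, samples_per_group=12, signature_effect=0.0,
        batch_effect_sd=0.0, outlier_fraction=0.0, seed=11,
    )
    return _prepare(cfg)
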