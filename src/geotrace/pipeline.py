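"""End-to-end orchestration: simulate -> preprocess -> select -> classify -> mystery.

A ``RunConfig`` gathers every stage's parameters and is archived (as YAML)
into the output directory together with all result tables, so a run is fully
reproducible from the archived config and seed.  Sub-stage seeds are derived
deterministically from the single top-level seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io, preprocess, synthetic
from .classify import (LearnerSpec, make_split_plan, per_group_error,
                       run_protocol, topk_error, year_confusion)
from .city_traits import discretize_city_traits
from .feature_select import (ElasticNetSpec, cutoff_sweep, fit_all_one_vs_rest,
                             retention_profile, select_by_cutoff)
from .mystery import (average_profiles, fit_multioutput_traits, match_pattern,
                      mystery_detection_rate, predict_traits,
                      run_mystery_protocol, trait_holdout_errors)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    out_dir: str = "geotrace_run"
    seed: int = 0
    # data source: either a simulation config or paths to user tables
    simulate: dict | None = None  # kwargs for synthetic.small_config/SimConfig
    counts_path: str | None = None
    meta_path: str | None = None
    # preprocessing
    depth_fraction: float = 0.2
    ubiquity_threshold: float = 0.6
    # feature selection
    alpha: float = 0.4
    n_cv_folds: int = 10
    cutoffs: list[int] = field(default_factory=lambda: list(range(6, 15)))
    chosen_cutoff: int | None = None  # None: lowest MLP top-1 error wins
    # classification protocol
    methods: list[str] = field(default_factory=lambda: ["rf", "svm", "mlp"])
    n_reps: int = 100
    test_frac: float = 0.2
    val_frac: float = 0.2
    # mystery stage (runs only when mystery data exists)
    mystery_reps: int = 100

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def _derive_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


def run_end_to_end(config: RunConfig) -> dict:
    """Execute the full workflow; returns the summary bundle (also on disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")
    summary: dict = {}

    # ---- stage 1: data --------------------------------------------------
    study = None
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", _derive_seed(config.seed, 1))
        if "years_per_city" in sim_kwargs:
            sim_cfg = synthetic.SimConfig(**sim_kwargs)
        else:
            sim_cfg = synthetic.small_config(**sim_kwargs)
        study = synthetic.simulate_study(sim_cfg)
        synthetic.write_study(study, out / "data")
        table, meta = study.counts, study.meta
    elif config.counts_path and config.meta_path:
        table = data_io.read_counts(config.counts_path)
        meta = data_io.read_metadata(config.meta_path)
    else:
        raise ValueError("config must provide either 'simulate' or data paths")
    index = data_io.build_group_index(meta)
    logger.info("stage data: %d samples, %d taxa, %d groups",
                table.n_samples, table.n_taxa, len(index.groups))

    # ---- stage 2: preprocess -------------------------------------------
    filtered, report = preprocess.order_sum_filter(
        table, index, fraction=config.depth_fraction)
    index = index.restrict(filtered.sample_ids)
    keep_taxa = preprocess.ubiquity_filter(
        filtered, threshold=config.ubiquity_threshold)
    filtered = filtered.subset_taxa(
        [t for t in filtered.taxon_ids if t in keep_taxa])
    X = preprocess.log2_cpm(filtered)
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t")
    summary["n_samples_before_filter"] = report.n_before
    summary["n_samples_after_filter"] = report.n_after
    summary["n_taxa_after_ubiquity"] = filtered.n_taxa
    logger.info("stage preprocess: %d -> %d samples, %d ubiquitous taxa",
                report.n_before, report.n_after, filtered.n_taxa)

    # ---- stage 3: feature selection ------------------------------------
    en_spec = ElasticNetSpec(alpha=config.alpha, n_cv_folds=config.n_cv_folds,
                             seed=_derive_seed(config.seed, 3))
    fits = fit_all_one_vs_rest(X, index, en_spec)
    profile = retention_profile(fits)
    profile.sort_values(ascending=False).to_csv(
        out / "retention_profile.tsv", sep="\t", header=True)

    plan = make_split_plan(index, test_frac=config.test_frac,
                           val_frac=config.val_frac, n_reps=config.n_reps,
                           seed=_derive_seed(config.seed, 4))
    sweep = cutoff_sweep(X, index, en_spec, config.cutoffs,
                         methods=tuple(config.methods), profile=profile,
                         plan=plan, seed=_derive_seed(config.seed, 5))
    sweep.to_csv(out / "cutoff_sweep.tsv", sep="\t")

    ref_method = "mlp" if "mlp" in config.methods else config.methods[-1]
    if config.chosen_cutoff is not None:
        cutoff = config.chosen_cutoff
    else:
        col = sweep[f"{ref_method}_top1"].dropna()
        cutoff = int(col.idxmin()) if len(col) else int(config.cutoffs[0])
    features = sorted(select_by_cutoff(profile, cutoff))
    if not features:
        raise RuntimeError(f"stage select: empty feature set at cutoff {cutoff}")
    (out / "selected_features.txt").write_text("\n".join(features) + "\n")
    summary["chosen_cutoff"] = cutoff
    summary["n_selected_features"] = len(features)
    logger.info("stage select: cutoff %d -> %d features", cutoff, len(features))

    # ---- stage 4: classification ---------------------------------------
    lspec = LearnerSpec(method=ref_method, seed=_derive_seed(config.seed, 6))
    tally = run_protocol(X[features], index, plan, lspec)
    tally.votes.to_csv(out / "vote_tally.tsv", sep="\t")
    err1, err2 = topk_error(tally, 1), topk_error(tally, 2)
    per_group = pd.DataFrame({
        "top1_error": per_group_error(tally, index, 1),
        "top2_error": per_group_error(tally, index, 2),
    })
    per_group.to_csv(out / "per_group_error.tsv", sep="\t")
    yc, yd = year_confusion(tally, index)
    summary.update({
        "method": ref_method, "top1_error": err1, "top2_error": err2,
        "year_confusion_count": yc, "year_confusion_denominator": yd,
    })
    logger.info("stage classify: top-1 %.4f, top-2 %.4f", err1, err2)

    # ---- stage 5: traits ------------------------------------------------
    if study is not None:
        climate, attributes = synthetic.generate_city_traits(sim_cfg, study.truth)
        profiles = discretize_city_traits(climate, attributes,
                                          seed=_derive_seed(config.seed, 7))
        profiles.to_csv(out / "city_trait_profiles.tsv", sep="\t")
        cities = meta.set_index("sample_id")["city"]
        cities = cities.loc[X.index]
        trait_err = trait_holdout_errors(
            X[features], cities, profiles,
            seed=_derive_seed(config.seed, 8))
        trait_err.to_csv(out / "trait_holdout_errors.tsv", sep="\t", header=True)
        summary["trait_errors"] = {t: float(v) for t, v in trait_err.items()}

        # ---- stage 6: mystery ------------------------------------------
        if study.mystery_counts is not None:
            mys_table = study.mystery_counts.subset_taxa(
                [t for t in study.mystery_counts.taxon_ids if t in set(features)])
            mys_X = preprocess.log2_cpm(mys_table)[features]
            m_meta = study.mystery_meta.set_index("sample_id")
            truth_labels = pd.Series(
                [g if m_meta.loc[s, "city"] not in study.truth.mystery_cities
                 else "mystery"
                 for s, g in m_meta["group"].items()],
                index=m_meta.index)
            mtally = run_mystery_protocol(
                X[features], index, mys_X,
                n_reps=config.mystery_reps,
                seed=_derive_seed(config.seed, 9),
                mystery_truth=truth_labels)
            mtally.votes.to_csv(out / "mystery_votes.tsv", sep="\t")
            unseen_ids = [s for s in mys_X.index
                          if m_meta.loc[s, "city"] in study.truth.mystery_cities]
            if unseen_ids:
                rate = mystery_detection_rate(mtally, unseen_ids)
                summary["mystery_detection_rate"] = rate
                model = fit_multioutput_traits(
                    X[features], cities, profiles,
                    seed=_derive_seed(config.seed, 10))
                preds = predict_traits(model, mys_X.loc[unseen_ids])
                avg = average_profiles(
                    preds, m_meta.loc[unseen_ids, "city"])
                avg.to_csv(out / "mystery_avg_profiles.tsv", sep="\t")
                ranks = []
                for city, row in avg.iterrows():
                    ranked = match_pattern(row, profiles)
                    ranked.insert(0, "query_city", city)
                    ranks.append(ranked.head(3))
                pd.concat(ranks).to_csv(
                    out / "mystery_candidates.tsv", sep="\t", index=False)
                logger.info("stage mystery: detection rate %.3f", rate)

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
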