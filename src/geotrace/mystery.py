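"""Origin inference for samples of unknown provenance.

Two complementary routes:

* *mystery-class augmentation*: in each repetition 20% of the unknown-origin
  samples are held out and the remainder are added to the full main-dataset
  training set under the extra label ``"mystery"``; an MLP is fitted and votes
  are accumulated for the held-out samples.  A sample whose top-voted class is
  ``"mystery"`` is flagged as coming from a city absent from the training data.
* *trait profiling*: a shared-trunk multi-output MLP (one softmax head per
  trait) maps microbial profiles to the six categorical city traits, with
  collection years merged.  Averaging per-sample predicted levels within a
  city gives a trait profile which is matched against the known cities'
  profiles (round each averaged level, then rank by L1 distance) to shortlist
  candidate origins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._mlp import MultiHeadMLP
from .city_traits import TRAIT_COLUMNS
from .classify import LearnerSpec, VoteTally, _round_half_up
from .data_io import GroupIndex

logger = logging.getLogger(__name__)

MYSTERY_LABEL = "mystery"


def _check_features(main_X: pd.DataFrame, mystery_X: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in main_X.columns if c not in mystery_X.columns]
    if missing:
        raise ValueError(
            f"mystery table is missing {len(missing)} taxa, e.g. {missing[:5]}"
        )
    return mystery_X[main_X.columns]


def run_mystery_protocol(
    main_X: pd.DataFrame,
    main_index: GroupIndex,
    mystery_X: pd.DataFrame,
    spec: LearnerSpec | None = None,
    n_reps: int = 100,
    test_frac: float = 0.2,
    seed: int = 0,
    mystery_truth: pd.Series | None = None,
) -> VoteTally:
    """Repeated mystery-class runs; votes accumulate over the reps in which a
    sample was held out, so each sample's votes sum to its hold-out count.
    """
    spec = spec or LearnerSpec(method="mlp")
    mystery_X = _check_features(main_X, mystery_X)
    rng = np.random.default_rng(seed)

    labels_main = main_index.labels_for(list(main_X.index)).to_numpy()
    Xmain = main_X.to_numpy(dtype=float)
    Xmys = mystery_X.to_numpy(dtype=float)
    n_mys = len(mystery_X)
    n_test = max(1, _round_half_up(test_frac * n_mys))
    classes = list(main_index.groups) + [MYSTERY_LABEL]

    votes = pd.DataFrame(
        0, index=pd.Index(mystery_X.index, name="sample_id"), columns=classes
    )
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    for r in range(n_reps):
        order = rng.permutation(n_mys)
        test_idx, train_idx = order[:n_test], order[n_test:]
        X_train = np.vstack([Xmain, Xmys[train_idx]])
        y_train = np.concatenate(
            [labels_main, np.repeat(MYSTERY_LABEL, len(train_idx))]
        )
        # carve a seeded 15% validation split for early stopping
        sub = int(seeds[r].generate_state(1)[0] % 2**31)
        vrng = np.random.default_rng(sub)
        vperm = vrng.permutation(len(y_train))
        n_val = max(1, len(y_train) * 15 // 100)
        va, tr = vperm[:n_val], vperm[n_val:]

        mlp = MultiHeadMLP(
            hidden_layer_sizes=spec.mlp_hidden, dropout=spec.mlp_dropout,
            epochs=spec.mlp_epochs, batch_size=spec.mlp_batch_size, seed=sub,
        )
        mlp.fit(X_train[tr], y_train[tr], X_train[va], y_train[va])
        pred = mlp.predict(Xmys[test_idx])
        for i, c in zip(test_idx, pred):
            votes.iloc[i, votes.columns.get_loc(c)] += 1

    if mystery_truth is None:
        mystery_truth = pd.Series(MYSTERY_LABEL, index=votes.index)
    return VoteTally(votes=votes, truth=mystery_truth.loc[votes.index])


def mystery_detection_rate(tally: VoteTally, unseen_ids: list[str]) -> float:
    """Fraction of unseen-city samples whose top-voted class is "mystery"."""
    if not unseen_ids:
        raise ValueError("no unseen-city samples supplied")
    sub = tally.votes.loc[list(unseen_ids)]
    top = sub.idxmax(axis=1)
    return float((top == MYSTERY_LABEL).mean())


# ----------------------------------------------------------------- traits

@dataclass
class TraitModel:
    """Fitted multi-output trait predictor (six softmax heads, shared trunk)."""

    mlp: MultiHeadMLP
    traits: list[str]
    level_sets: dict[str, list[int]]


def _trait_targets(cities: pd.Series, profiles: pd.DataFrame) -> np.ndarray:
    missing = sorted(set(cities) - set(profiles.index))
    if missing:
        raise ValueError(f"cities without a trait profile: {missing}")
    for t in TRAIT_COLUMNS:
        if t not in profiles.columns:
            raise ValueError(f"profile table missing trait {t!r}")
    return profiles.loc[cities, TRAIT_COLUMNS].to_numpy(dtype=int)


def fit_multioutput_traits(
    X: pd.DataFrame,
    cities: pd.Series,
    profiles: pd.DataFrame,
    spec: LearnerSpec | None = None,
    seed: int = 0,
    val_frac: float = 0.15,
) -> TraitModel:
    """Train the six-head trait network on per-sample data with city-level labels.

    ``cities`` maps each sample to its city (collection years merged: samples
    of one city share labels regardless of year).
    """
    spec = spec or LearnerSpec(method="mlp")
    Y = _trait_targets(cities.loc[X.index], profiles)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_val = max(1, int(round(val_frac * len(X))))
    va, tr = perm[:n_val], perm[n_val:]
    Xm = X.to_numpy(dtype=float)

    mlp = MultiHeadMLP(
        hidden_layer_sizes=spec.mlp_hidden, dropout=spec.mlp_dropout,
        epochs=spec.mlp_epochs, batch_size=spec.mlp_batch_size, seed=seed,
    )
    mlp.fit(Xm[tr], Y[tr], Xm[va], Y[va])
    level_sets = {
        t: sorted(int(v) for v in profiles[t].unique()) for t in TRAIT_COLUMNS
    }
    return TraitModel(mlp=mlp, traits=list(TRAIT_COLUMNS), level_sets=level_sets)


def predict_traits(model: TraitModel, X: pd.DataFrame) -> pd.DataFrame:
    """Per-sample predicted level for each of the six traits."""
    pred = model.mlp.predict(X.to_numpy(dtype=float))
    return pd.DataFrame(pred, index=X.index, columns=model.traits).astype(int)


def trait_holdout_errors(
    X: pd.DataFrame,
    cities: pd.Series,
    profiles: pd.DataFrame,
    spec: LearnerSpec | None = None,
    test_frac: float = 0.2,
    seed: int = 0,
) -> pd.Series:
    """Per-trait misclassification rate on a city-stratified held-out split."""
    rng = np.random.default_rng(seed)
    cities = cities.loc[X.index]
    test: list[str] = []
    for _, sub in cities.groupby(cities):
        ids = list(sub.index)
        order = rng.permutation(len(ids))
        n_test = max(1, _round_half_up(test_frac * len(ids)))
        test.extend(ids[i] for i in order[:n_test])
    train = [s for s in X.index if s not in set(test)]

    model = fit_multioutput_traits(X.loc[train], cities, profiles,
                                   spec=spec, seed=seed)
    pred = predict_traits(model, X.loc[test])
    true = pd.DataFrame(
        _trait_targets(cities.loc[test], profiles),
        index=test, columns=TRAIT_COLUMNS,
    )
    return pd.Series(
        {t: float((pred[t] != true[t]).mean()) for t in TRAIT_COLUMNS},
        name="error_rate",
    )


def average_profiles(predictions: pd.DataFrame, cities: pd.Series) -> pd.DataFrame:
    """Arithmetic mean of predicted levels per city per trait."""
    df = predictions.copy()
    df["city"] = cities.loc[predictions.index].to_numpy()
    return df.groupby("city").mean()


def match_pattern(
    avg_profile: pd.Series | np.ndarray,
    known_profiles: pd.DataFrame,
) -> pd.DataFrame:
    """Rank known cities by L1 distance to the rounded averaged profile.

    Ties share the same distance and are returned adjacent (stable city order).
    """
    if isinstance(avg_profile, pd.Series):
        query = avg_profile[list(known_profiles.columns)].to_numpy(dtype=float)
    else:
        query = np.asarray(avg_profile, dtype=float)
    rounded = np.round(query).astype(int)
    dists = np.abs(known_profiles.to_numpy(dtype=int) - rounded).sum(axis=1)
    out = pd.DataFrame(
        {"city": known_profiles.index, "distance": dists}
    ).sort_values(["distance", "city"], kind="stable").reset_index(drop=True)
    return out
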