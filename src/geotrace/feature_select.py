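"""One-vs-rest elastic-net retention counting and cutoff-based feature sets.

For each city-year group a binomial elastic-net model (mixing parameter
alpha = 0.4 by default, penalty strength lambda chosen by cross-validated
deviance) is fitted against "all other groups".  A taxon's *retention count*
is the number of one-vs-rest models in which it received a nonzero
coefficient; ordering taxa by this count and thresholding it ("retained by at
least `cutoff` of the models") yields nested candidate feature sets whose
classification performance is compared in a cutoff sweep.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

from .data_io import GroupIndex

logger = logging.getLogger(__name__)


@dataclass
class ElasticNetSpec:
    """Settings shared by all one-vs-rest fits.

    ``lambda_grid=None`` means a glmnet-style data-driven grid searched by
    cross-validation (minimum mean binomial deviance); an explicit sequence
    bypasses the grid construction, and a single value skips CV entirely.
    """

    alpha: float = 0.4
    lambda_grid: list[float] | None = None
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-3
    n_cv_folds: int = 10
    standardize: bool = True
    class_weight: str | None = None  # None (unweighted) or "balanced"
    max_iter: int = 3000
    tol: float = 1e-3
    seed: int = 0


@dataclass
class ElasticNetFit:
    target_group: str
    intercept: float
    coef: pd.Series  # per-taxon coefficient (standardized scale)
    lambda_: float
    alpha: float

    @property
    def retained(self) -> set[str]:
        return set(self.coef.index[self.coef.to_numpy() != 0])


def _lambda_grid(Xs: np.ndarray, y: np.ndarray, spec: ElasticNetSpec) -> np.ndarray:
    """glmnet-style grid: geometric from lambda_max down to a fixed ratio."""
    n = len(y)
    resid = y - y.mean()
    l1_frac = max(spec.alpha, 1e-3)  # alpha=0 has no finite lambda_max
    lam_max = float(np.abs(Xs.T @ resid).max()) / (n * l1_frac)
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * spec.lambda_min_ratio, spec.n_lambda)


def fit_one_vs_rest(
    X: pd.DataFrame,
    index: GroupIndex,
    target_group: str,
    spec: ElasticNetSpec | None = None,
) -> ElasticNetFit:
    """Fit target-group-vs-rest penalized logistic regression on log2-CPM data."""
    spec = spec or ElasticNetSpec()
    members = set(index.members[target_group])
    y = np.array([1 if s in members else 0 for s in X.index])
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"group {target_group!r} needs >= 2 samples in and out of the group "
            f"(got {n_pos} in, {n_neg} out)"
        )

    Xm = X.to_numpy(dtype=float)
    if spec.standardize:
        mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
        sd[sd == 0] = 1.0
        Xm = (Xm - mu) / sd

    grid = (np.asarray(spec.lambda_grid, dtype=float)
            if spec.lambda_grid is not None else _lambda_grid(Xm, y, spec))

    n = len(y)
    if len(grid) == 1:
        lam = float(grid[0])
        model = _plain_fit(Xm, y, lam, spec)
        coef, intercept = model.coef_[0], float(model.intercept_[0])
        return ElasticNetFit(target_group, intercept,
                             pd.Series(coef, index=X.columns), lam, spec.alpha)

    Cs = 1.0 / (n * np.sort(grid)[::-1])  # strong -> weak penalty
    n_splits = max(2, min(spec.n_cv_folds, n_pos, n_neg))
    cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=spec.seed)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = LogisticRegressionCV(
                Cs=Cs,
                l1_ratios=[spec.alpha],
                solver="saga",
                cv=cv,
                scoring="neg_log_loss",
                class_weight=spec.class_weight,
                max_iter=spec.max_iter,
                tol=spec.tol,
                random_state=spec.seed,
                use_legacy_attributes=True,
            )
            model.fit(Xm, y)
        chosen_C = float(np.ravel(model.C_)[0])
        coef = model.coef_[0]
        if not np.all(np.isfinite(coef)):
            raise FloatingPointError("non-finite coefficients")
    except Exception as exc:  # degenerate/separated fit: 1-SE-style fallback
        logger.warning(
            "one-vs-rest fit for %s failed (%s); refitting at the strongest "
            "grid penalty within one SE of the median", target_group, exc,
        )
        lam = float(np.median(grid))
        model = _plain_fit(Xm, y, lam, spec)
        return ElasticNetFit(target_group, float(model.intercept_[0]),
                             pd.Series(model.coef_[0], index=X.columns),
                             lam, spec.alpha)

    lam = 1.0 / (n * chosen_C)
    return ElasticNetFit(target_group, float(model.intercept_[0]),
                         pd.Series(coef, index=X.columns), lam, spec.alpha)


def _plain_fit(Xm, y, lam: float, spec: ElasticNetSpec) -> LogisticRegression:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if lam == 0:
            model = LogisticRegression(
                C=np.inf, solver="saga", max_iter=spec.max_iter, tol=spec.tol,
                class_weight=spec.class_weight, random_state=spec.seed,
            )
        else:
            model = LogisticRegression(
                C=1.0 / (len(y) * lam), l1_ratio=spec.alpha, solver="saga",
                max_iter=spec.max_iter, tol=spec.tol,
                class_weight=spec.class_weight, random_state=spec.seed,
            )
        model.fit(Xm, y)
    return model


def fit_all_one_vs_rest(
    X: pd.DataFrame, index: GroupIndex, spec: ElasticNetSpec | None = None
) -> list[ElasticNetFit]:
    """One elastic-net fit per city-year group (e.g. 28 models for 23 cities)."""
    return [fit_one_vs_rest(X, index, g, spec) for g in index.groups]


def retention_profile(fits: list[ElasticNetFit]) -> pd.Series:
    """Per-taxon count of one-vs-rest models retaining the taxon (Fig.-2 style)."""
    if not fits:
        raise ValueError("no fits")
    taxa = list(fits[0].coef.index)
    for f in fits[1:]:
        if list(f.coef.index) != taxa:
            raise ValueError("fits do not share a common feature set")
    counts = sum((f.coef.to_numpy() != 0).astype(int) for f in fits)
    return pd.Series(counts, index=taxa, name="retention_count")


def select_by_cutoff(profile: pd.Series, cutoff: int) -> set[str]:
    """Taxa retained by at least ``cutoff`` one-vs-rest models."""
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    return set(profile.index[profile.to_numpy() >= cutoff])


def cutoff_sweep(
    X: pd.DataFrame,
    index: GroupIndex,
    spec: ElasticNetSpec | None,
    cutoffs: list[int],
    methods: tuple[str, ...] = ("rf", "svm", "mlp"),
    *,
    profile: pd.Series | None = None,
    plan=None,
    n_reps: int = 100,
    seed: int = 0,
    learner_overrides: dict | None = None,
) -> pd.DataFrame:
    """Classification error per (cutoff, method) under the repeated-split protocol.

    Returns one row per cutoff with the feature-set size and each method's
    top-1 and top-2 vote error; cutoffs with an empty feature set get NA errors.
    """
    from .classify import LearnerSpec, make_split_plan, run_protocol, topk_error

    if profile is None:
        profile = retention_profile(fit_all_one_vs_rest(X, index, spec))
    if plan is None:
        plan = make_split_plan(index, n_reps=n_reps, seed=seed)

    rows = []
    for cutoff in cutoffs:
        feats = sorted(select_by_cutoff(profile, cutoff))
        row: dict = {"cutoff": cutoff, "n_features": len(feats)}
        for method in methods:
            if not feats:
                row[f"{method}_top1"] = np.nan
                row[f"{method}_top2"] = np.nan
                continue
            lspec = LearnerSpec(method=method, seed=seed,
                                **(learner_overrides or {}))
            tally = run_protocol(X[feats], index, plan, lspec)
            row[f"{method}_top1"] = topk_error(tally, 1)
            row[f"{method}_top2"] = topk_error(tally, 2)
        rows.append(row)
    return pd.DataFrame(rows).set_index("cutoff")
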