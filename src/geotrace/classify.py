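"""Repeated-split classification protocol with ensemble vote aggregation.

20% of each city-year group is held out once as a fixed test set; the
remainder is re-partitioned 80/20 into training and validation sets in each
of ``n_reps`` repetitions (100 by default).  Each repetition fits a learner
(random forest, RBF support-vector machine, or multilayer perceptron) and
casts one vote per test sample; errors are computed from the accumulated
votes, counting a sample as correct when its true group holds the highest
(top-1) or one of the two highest distinct (top-2) vote ranks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._mlp import MultiHeadMLP
from .data_io import GroupIndex

logger = logging.getLogger(__name__)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class SplitPlan:
    """Fixed test set plus per-repetition train/validation partitions."""

    test: list[str]
    reps: list[tuple[list[str], list[str]]]  # (train, validation) per rep
    n_reps: int
    seed: int


@dataclass
class LearnerSpec:
    """Hyperparameters for the three learner back-ends."""

    method: str = "mlp"  # rf | svm | mlp
    # random forest
    rf_n_trees: int = 1000  # mtry is sqrt(p), the randomForest default
    # SVM: RBF kernel, grid chosen on validation accuracy
    svm_gamma_grid: tuple[float, ...] = (1e-3, 1e-2, 1e-1, 1e0, 1e1)
    svm_cost_grid: tuple[float, ...] = (1e-1, 1e0, 1e1, 1e2, 1e3)
    # MLP: ReLU trunk, softmax output, dropout, early stopping on validation
    mlp_hidden: tuple[int, ...] = (64, 32)
    mlp_dropout: float = 0.3
    mlp_epochs: int = 300
    mlp_batch_size: int = 32
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in {"rf", "svm", "mlp"}:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass
class VoteTally:
    """Accumulated per-class votes for each test sample, plus the truth."""

    votes: pd.DataFrame  # test samples x classes, integer votes
    truth: pd.Series  # true class label per test sample

    def __post_init__(self) -> None:
        if not self.votes.index.equals(self.truth.index):
            raise ValueError("votes and truth must share the sample index")


def make_split_plan(
    index: GroupIndex,
    test_frac: float = 0.2,
    val_frac: float = 0.2,
    n_reps: int = 100,
    seed: int = 0,
) -> SplitPlan:
    """Group-stratified fixed test set and repeated train/validation splits.

    Per group the test size is round-half-up(test_frac x size) with a minimum
    of one sample; per repetition the validation size is
    round-half-up(val_frac x remainder) and may be zero for tiny groups.
    """
    rng = np.random.default_rng(seed)
    test: list[str] = []
    pools: dict[str, list[str]] = {}
    for g in index.groups:
        members = list(index.members[g])
        if len(members) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")
        order = rng.permutation(len(members))
        n_test = max(1, _round_half_up(test_frac * len(members)))
        test.extend(members[i] for i in order[:n_test])
        pools[g] = [members[i] for i in order[n_test:]]
        if len(pools[g]) < 2:
            logger.warning("group %s: only %d non-test sample(s); validation "
                           "splits may be empty", g, len(pools[g]))

    reps = []
    for _ in range(n_reps):
        train: list[str] = []
        val: list[str] = []
        for g in index.groups:
            pool = pools[g]
            order = rng.permutation(len(pool))
            n_val = _round_half_up(val_frac * len(pool))
            n_val = min(n_val, max(0, len(pool) - 2))  # keep >= 2 to train on
            val.extend(pool[i] for i in order[:n_val])
            train.extend(pool[i] for i in order[n_val:])
        reps.append((train, val))
    return SplitPlan(test=test, reps=reps, n_reps=n_reps, seed=seed)


def _fit_predict(
    method: str,
    spec: LearnerSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    X_test: np.ndarray,
    seed: int,
) -> np.ndarray:
    if method == "rf":
        rf = RandomForestClassifier(
            n_estimators=spec.rf_n_trees, max_features="sqrt",
            random_state=seed, n_jobs=1,
        )
        rf.fit(X_train, y_train)
        return rf.predict(X_test)

    if method == "svm":
        scaler = StandardScaler().fit(X_train)
        Xtr, Xte = scaler.transform(X_train), scaler.transform(X_test)
        best, best_acc = None, -1.0
        if len(X_val):
            Xv = scaler.transform(X_val)
            for gamma in spec.svm_gamma_grid:
                for cost in spec.svm_cost_grid:
                    m = SVC(kernel="rbf", gamma=gamma, C=cost, random_state=seed)
                    m.fit(Xtr, y_train)
                    acc = float(np.mean(m.predict(Xv) == y_val))
                    if acc > best_acc:
                        best, best_acc = m, acc
        else:
            best = SVC(kernel="rbf", gamma="scale", C=1.0,
                       random_state=seed).fit(Xtr, y_train)
        return best.predict(Xte)

    mlp = MultiHeadMLP(
        hidden_layer_sizes=spec.mlp_hidden, dropout=spec.mlp_dropout,
        epochs=spec.mlp_epochs, batch_size=spec.mlp_batch_size, seed=seed,
    )
    mlp.fit(X_train, y_train,
            X_val if len(X_val) else None, y_val if len(y_val) else None)
    return mlp.predict(X_test)


def run_protocol(
    X: pd.DataFrame,
    index: GroupIndex,
    plan: SplitPlan,
    spec: LearnerSpec,
) -> VoteTally:
    """Fit the learner once per repetition and accumulate test-set votes."""
    labels = index.labels_for(list(X.index))
    Xm = X.to_numpy(dtype=float)
    pos = {s: i for i, s in enumerate(X.index)}
    classes = list(index.groups)
    votes = pd.DataFrame(
        0, index=pd.Index(plan.test, name="sample_id"), columns=classes
    )
    test_idx = np.array([pos[s] for s in plan.test])
    X_test = Xm[test_idx]

    seeds = np.random.SeedSequence(spec.seed).spawn(10 * plan.n_reps)
    failures = 0
    for r, (train, val) in enumerate(plan.reps):
        tr = np.array([pos[s] for s in train])
        va = np.array([pos[s] for s in val], dtype=int)
        attempt = 0
        while True:
            sub = int(seeds[r * 10 + attempt].generate_state(1)[0] % 2**31)
            try:
                pred = _fit_predict(
                    spec.method, spec, Xm[tr], labels.iloc[tr].to_numpy(),
                    Xm[va] if len(va) else np.empty((0, Xm.shape[1])),
                    labels.iloc[va].to_numpy() if len(va) else np.array([]),
                    X_test, sub,
                )
                break
            except Exception as exc:
                failures += 1
                attempt += 1
                logger.warning("rep %d failed (%s); retrying", r, exc)
                if failures > 5:
                    raise RuntimeError(
                        f"more than 5 learner failures; aborting at rep {r}"
                    ) from exc
        for s, c in zip(plan.test, pred):
            votes.loc[s, c] += 1

    truth = labels.loc[plan.test]
    return VoteTally(votes=votes, truth=truth)


def _correct_mask(tally: VoteTally, k: int) -> pd.Series:
    """Per-sample correctness under the top-k vote rule.

    k=1: correct iff the truth is among the classes with the maximum vote.
    k=2: correct iff the truth is among the classes holding the two highest
    distinct vote ranks; classes with zero votes never hold a rank.
    """
    if k not in (1, 2):
        raise ValueError("k must be 1 or 2")
    v = tally.votes.to_numpy()
    out = []
    for i, truth in enumerate(tally.truth):
        row = v[i]
        nz = np.unique(row[row > 0])[::-1]  # distinct positive votes, desc
        top_vals = nz[:k]
        winners = {
            c for c, x in zip(tally.votes.columns, row) if x in top_vals
        }
        out.append(truth in winners)
    return pd.Series(out, index=tally.truth.index)


def topk_error(tally: VoteTally, k: int = 1) -> float:
    """Overall test error under the top-k vote rule."""
    if len(tally.truth) == 0:
        raise ValueError("empty tally")
    return float(1.0 - _correct_mask(tally, k).mean())


def per_group_error(tally: VoteTally, index: GroupIndex, k: int = 1) -> pd.Series:
    """Top-k error restricted to each group's test samples (NA if none)."""
    correct = _correct_mask(tally, k)
    groups = index.labels_for(list(tally.truth.index))
    out = {}
    for g in index.groups:
        mask = groups == g
        out[g] = float(1.0 - correct[mask].mean()) if mask.any() else np.nan
    return pd.Series(out, name=f"top{k}_error")


def year_confusion(tally: VoteTally, index: GroupIndex) -> tuple[int, int]:
    """Same-city-different-year confusions among multi-year-city test samples.

    Returns (count, denominator): the denominator is the number of test
    samples whose city was sampled in more than one year; the count is how
    many of those received their top vote for the same city in another year.
    """
    city_of = {g: index.group_meta[g][0] for g in index.groups}
    years_per_city: dict[str, set[int]] = {}
    for g in index.groups:
        c, y = index.group_meta[g]
        years_per_city.setdefault(c, set()).add(y)
    multi = {c for c, ys in years_per_city.items() if len(ys) > 1}
    if not multi:
        return 0, 0

    top = tally.votes.idxmax(axis=1)  # deterministic: first column on ties
    count = denom = 0
    for s, truth in tally.truth.items():
        if city_of[truth] not in multi:
            continue
        denom += 1
        pred = top.loc[s]
        if pred != truth and city_of[pred] == city_of[truth]:
            count += 1
    return count, denom
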