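import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from geotrace import LearnerSpec, build_group_index, make_split_plan, \
    per_group_error, run_protocol, topk_error, year_confusion
from geotrace.classify import VoteTally


def _index(group_sizes, years=None):
    rows = []
    for gi, size in enumerate(group_sizes):
        city = f"C{gi:02d}" if years is None else years[gi][0]
        year = 2017 if years is None else years[gi][1]
        rows += [{"sample_id": f"{city}_{year}_{i}", "city": city, "year": year}
                 for i in range(size)]
    return build_group_index(pd.DataFrame(rows))


def test_split_plan_sizes_follow_rounding_rule():
    index = _index([10])
    plan = make_split_plan(index, n_reps=3, seed=0)
    assert len(plan.test) == 2  # round(0.2 * 10)
    for train, val in plan.reps:
        assert len(val) == 2  # round(0.2 * 8)
        assert len(train) == 6


def test_split_plan_partitions_are_disjoint_and_fixed():
    index = _index([10, 7, 5, 23])
    plan = make_split_plan(index, n_reps=10, seed=1)
    test = set(plan.test)
    all_samples = {s for g in index.groups for s in index.members[g]}
    for train, val in plan.reps:
        train, val = set(train), set(val)
        assert not (test & (train | val))
        assert not (train & val)
        assert test | train | val == all_samples
    # at least one test sample per group, ~20% overall
    for g in index.groups:
        assert test & set(index.members[g])
    # deterministic given seed
    plan2 = make_split_plan(index, n_reps=10, seed=1)
    assert plan2.test == plan.test and plan2.reps == plan.reps


def test_split_plan_requires_three_samples_per_group():
    with pytest.raises(ValueError, match="fewer than 3"):
        make_split_plan(_index([10, 2]))


def _tally(rows, truths):
    votes = pd.DataFrame(rows).T
    votes.index.name = "sample_id"
    truth = pd.Series(truths)
    return VoteTally(votes=votes, truth=truth)


def test_topk_error_rank_rules():
    tally = _tally(
        {"s1": {"A": 60, "B": 40, "C": 0},
         "s2": {"A": 60, "B": 40, "C": 0},
         "s3": {"A": 50, "B": 50, "C": 0}},
        {"s1": "A", "s2": "B", "s3": "B"},
    )
    # s1: truth has strictly most votes -> correct under both rules
    # s2: truth holds the second-highest rank -> top-1 wrong, top-2 right
    # s3: tie at the top -> truth in the argmax set, correct under top-1
    assert topk_error(tally, 1) == pytest.approx(1 / 3)
    assert topk_error(tally, 2) == pytest.approx(0.0)


def test_topk_zero_vote_classes_hold_no_rank():
    tally = _tally({"s1": {"A": 10, "B": 0, "C": 0}}, {"s1": "B"})
    assert topk_error(tally, 2) == 1.0  # B was never voted for


@settings(max_examples=100, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_top2_error_never_exceeds_top1_on_random_tallies(seed):
    rng = np.random.default_rng(seed)
    n, g, reps = rng.integers(1, 8), rng.integers(2, 6), int(rng.integers(1, 30))
    classes = [f"G{j}" for j in range(g)]
    votes = rng.multinomial(reps, np.ones(g) / g, size=n)
    tally = VoteTally(
        votes=pd.DataFrame(votes, columns=classes,
                           index=[f"s{i}" for i in range(n)]),
        truth=pd.Series(rng.choice(classes, n), index=[f"s{i}" for i in range(n)]),
    )
    assert (tally.votes.sum(axis=1) == reps).all()
    assert topk_error(tally, 2) <= topk_error(tally, 1)


def test_per_group_error_weighted_mean_identity():
    index = _index([3, 3])
    g0, g1 = index.groups
    samples = index.members[g0][:2] + index.members[g1][:1]
    votes = pd.DataFrame(
        [[5, 0], [0, 5], [0, 5]], columns=[g0, g1],
        index=pd.Index(samples, name="sample_id"),
    )
    truth = pd.Series([g0, g0, g1], index=samples)
    tally = VoteTally(votes=votes, truth=truth)
    per_group = per_group_error(tally, index, k=1)
    assert per_group[g0] == pytest.approx(0.5)
    assert per_group[g1] == pytest.approx(0.0)
    sizes = pd.Series({g0: 2, g1: 1})
    weighted = (per_group * sizes).sum() / sizes.sum()
    assert weighted == pytest.approx(topk_error(tally, 1))


def test_year_confusion_counts_same_city_other_year():
    index = _index([3, 3, 3], years=[("NYC", 2016), ("NYC", 2017),
                                     ("LIS", 2016)])
    s_nyc16 = index.members["NYC_16"][0]
    s_nyc17 = index.members["NYC_17"][0]
    s_lis = index.members["LIS_16"][0]
    votes = pd.DataFrame(
        [[0, 9, 0], [0, 9, 0], [9, 0, 0]],
        columns=["NYC_16", "NYC_17", "LIS_16"],
        index=pd.Index([s_nyc16, s_nyc17, s_lis], name="sample_id"),
    )
    truth = pd.Series(["NYC_16", "NYC_17", "LIS_16"],
                      index=[s_nyc16, s_nyc17, s_lis])
    tally = VoteTally(votes=votes, truth=truth)
    count, denom = year_confusion(tally, index)
    assert (count, denom) == (1, 2)  # nyc16 voted NYC_17; lis not multi-year


def test_year_confusion_without_multiyear_cities():
    index = _index([3, 3])
    samples = [index.members[g][0] for g in index.groups]
    votes = pd.DataFrame([[1, 0], [0, 1]], columns=index.groups,
                         index=pd.Index(samples, name="sample_id"))
    tally = VoteTally(votes=votes,
                      truth=pd.Series(index.groups, index=samples))
    assert year_confusion(tally, index) == (0, 0)


@pytest.mark.parametrize("method, overrides", [
    ("mlp", {"mlp_epochs": 120}),
    ("rf", {"rf_n_trees": 50}),
    ("svm", {"svm_gamma_grid": (0.01, 0.1), "svm_cost_grid": (1.0, 10.0)}),
])
def test_separable_data_gets_unanimous_correct_votes(strong_study, method,
                                                     overrides):
    s = strong_study
    plan = make_split_plan(s.index, n_reps=3, seed=2)
    spec = LearnerSpec(method=method, seed=0, **overrides)
    tally = run_protocol(s.X, s.index, plan, spec)
    assert (tally.votes.sum(axis=1) == plan.n_reps).all()
    for sample, truth in tally.truth.items():
        assert tally.votes.loc[sample, truth] == plan.n_reps
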