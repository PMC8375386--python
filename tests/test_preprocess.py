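import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from geotrace import build_group_index, log2_cpm, order_sum_filter, \
    ubiquity_filter
from geotrace.data_io import OtuTable


def _one_group_table(order_sums):
    """One-city table whose per-sample order sums are as given."""
    ids = [f"s{i}" for i in range(len(order_sums))]
    counts = np.array(order_sums, dtype=int).reshape(-1, 1)
    table = OtuTable(ids, ["o__A"], counts)
    meta = pd.DataFrame({"sample_id": ids, "city": "AAA", "year": 2017})
    return table, build_group_index(meta)


@pytest.mark.parametrize(
    "sums, expected_removed",
    [
        ([100, 90, 110, 15], ["s3"]),  # median 95, cutoff 19
        ([100, 100, 100, 100, 10], ["s4"]),  # cutoff 20
        ([50, 50, 50, 50], []),  # equal depth: nobody removed
        ([100, 100, 100, 20], []),  # exactly at 20% of median: retained
    ],
)
def test_order_sum_filter_hand_computed(sums, expected_removed):
    table, index = _one_group_table(sums)
    filtered, report = order_sum_filter(table, index, fraction=0.2)
    assert report.removed == expected_removed
    assert set(report.removed) | set(filtered.sample_ids) == set(table.sample_ids)
    assert report.n_after == report.n_before - len(expected_removed)


def test_order_sum_filter_cutoff_is_exact_fraction_of_median():
    table, index = _one_group_table([100, 90, 110, 15])
    _, report = order_sum_filter(table, index, fraction=0.2)
    assert report.group_cutoff["AAA_17"] == 0.2 * report.group_median["AAA_17"]
    assert report.group_median["AAA_17"] == 95.0


def test_order_sum_filter_uses_order_rank_only():
    ids = ["s0", "s1", "s2", "s3"]
    counts = np.array([[100, 0], [100, 0], [100, 0], [10, 100000]])
    table = OtuTable(ids, ["o__A", "s__B"], counts)
    meta = pd.DataFrame({"sample_id": ids, "city": "AAA", "year": 2017})
    _, report = order_sum_filter(table, build_group_index(meta))
    assert report.removed == ["s3"]  # huge species count does not rescue it


@pytest.mark.parametrize(
    "n_present, n_samples, kept",
    [(61, 100, True), (60, 100, False), (100, 100, True), (3, 5, False)],
)
def test_ubiquity_boundary_is_strict(n_present, n_samples, kept):
    ids = [f"s{i}" for i in range(n_samples)]
    col = np.array([1] * n_present + [0] * (n_samples - n_present)).reshape(-1, 1)
    table = OtuTable(ids, ["o__A"], col)
    assert (("o__A" in ubiquity_filter(table, threshold=0.6)) is kept)


def test_ubiquity_on_empty_table_raises():
    table = OtuTable([], ["o__A"], np.empty((0, 1), dtype=int))
    with pytest.raises(ValueError, match="empty"):
        ubiquity_filter(table)


def test_log2_cpm_forced_values():
    table = OtuTable(
        ["s1", "s2"], ["o__A", "o__B"],
        np.array([[0, 999_999], [2, 2_499_997]]),
    )
    X = log2_cpm(table)
    assert X.loc["s1", "o__A"] == pytest.approx(-1.0, abs=1e-12)  # log2(0.5)
    assert X.loc["s2", "o__A"] == pytest.approx(0.0, abs=1e-12)  # log2(1)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_log2_cpm_matches_closed_form_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    n, p = rng.integers(2, 8), rng.integers(1, 10)
    counts = rng.integers(0, 5000, size=(n, p))
    counts[:, 0] += 1  # nonzero library sizes
    table = OtuTable([f"s{i}" for i in range(n)],
                     [f"o__T{j}" for j in range(p)], counts)
    X = log2_cpm(table).to_numpy()
    lib = counts.sum(axis=1, keepdims=True)
    expected = np.log2((counts + 0.5) / (lib + 1) * 1e6)
    assert np.abs(X - expected).max() < 1e-12
    # strictly increasing in count at fixed library size
    order = np.argsort(counts, axis=1)
    for i in range(n):
        sorted_counts = counts[i, order[i]]
        sorted_vals = X[i, order[i]]
        increases = np.diff(sorted_counts) > 0
        assert np.all(np.diff(sorted_vals)[increases] > 0)


def test_log2_cpm_zero_library_raises():
    table = OtuTable(["s1"], ["o__A"], np.array([[0]]))
    with pytest.raises(ValueError, match="s1"):
        log2_cpm(table)
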