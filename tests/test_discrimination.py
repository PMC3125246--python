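"""KS testing, OR-combined pairwise discrimination, and trend profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cellgraphs import ks_two_sample, pairwise_discrimination, trend_profile
from cellgraphs.metrics import LABEL_COLUMNS, METRIC_NAMES

import oracles


def test_ks_identical_samples():
    x = [1.0, 2.0, 3.0, 4.0]
    res = ks_two_sample(x, x)
    assert res.statistic == 0.0 and res.reject == 0


def test_ks_fully_separated_samples(rng):
    x = rng.uniform(0, 1, 30)
    y = rng.uniform(5, 6, 30)
    res = ks_two_sample(x, y)
    assert res.statistic == 1.0 and res.reject == 1


def test_ks_interleaved_example():
    x = [1, 2, 3, 4, 5]
    y = [1.5, 2.5, 3.5, 4.5, 5.5]
    res = ks_two_sample(x, y)
    assert res.statistic == pytest.approx(0.2)
    assert res.statistic == pytest.approx(oracles.ks_statistic(x, y))


def test_ks_statistic_matches_brute_force_and_scipy(rng):
    for _ in range(20):
        x = rng.standard_normal(int(rng.integers(5, 40)))
        y = rng.standard_normal(int(rng.integers(5, 40))) + rng.uniform(-1, 1)
        res = ks_two_sample(x, y)
        assert res.statistic == pytest.approx(oracles.ks_statistic(list(x), list(y)))
        scipy_res = stats.ks_2samp(x, y, method="asymp")
        assert res.statistic == pytest.approx(scipy_res.statistic)
        # classical Kolmogorov-limit p with effective size nm/(n+m)
        ne = len(x) * len(y) / (len(x) + len(y))
        assert res.p_value == pytest.approx(
            stats.kstwobign.sf(np.sqrt(ne) * res.statistic), abs=1e-10
        )
        # scipy's asymptotic variant uses a refined approximation; the two
        # agree as approximations of the same limit
        assert res.p_value == pytest.approx(scipy_res.pvalue, abs=0.15)


def test_ks_validation():
    with pytest.raises(ValueError):
        ks_two_sample([], [1.0])
    with pytest.raises(ValueError):
        ks_two_sample([1.0], [2.0], alpha=1.5)


def test_ks_type_one_error_roughly_calibrated(rng):
    """Null rejection rate at the 10% level sits near the discrete test's
    attainable size (~7%) for n = 30 vs 30."""
    rejections = sum(
        ks_two_sample(rng.standard_normal(30), rng.standard_normal(30)).reject
        for _ in range(500)
    )
    assert 0.03 <= rejections / 500 <= 0.14


def _metric_table(per_line_shift, n_rep=5, times=(10.0, 16.0, 24.0), seed=0):
    """Table where metric columns are normal with a per-line mean shift."""
    rng = np.random.default_rng(seed)
    rows = []
    for line, shift in per_line_shift.items():
        for t in times:
            for r in range(1, n_rep + 1):
                vals = rng.standard_normal(20) + np.asarray(shift)
                row = dict(zip(METRIC_NAMES, vals))
                row.update(sample_id=f"{line}_{t}_{r}", cell_line=line,
                           time_h=t, replicate=r)
                rows.append(row)
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + METRIC_NAMES)


def test_pairwise_matrix_contracts():
    shift_a = np.zeros(20)
    shift_b = np.zeros(20)
    shift_b[0] = 5.0  # differs on one metric only: OR semantics must flag
    table = _metric_table({"a": shift_a, "b": shift_b, "c": shift_a}, seed=1)
    subset = METRIC_NAMES[:3]
    m = pairwise_discrimination(table, subset, alpha=0.10)
    assert np.array_equal(m.matrix, m.matrix.T)
    assert np.all(np.diag(m.matrix) == 0)
    assert m.pair("a", "b") == 1


def test_or_combination_dominates_single_metric():
    """The OR over metrics rejects whenever any single metric rejects."""
    shift = np.zeros(20)
    shift[2] = 4.0
    table = _metric_table({"a": np.zeros(20), "b": shift}, seed=2)
    single = pairwise_discrimination(table, [METRIC_NAMES[2]])
    combined = pairwise_discrimination(table, METRIC_NAMES[:5])
    assert combined.pair("a", "b") >= single.pair("a", "b") == 1


def test_matrix_invariant_to_line_ordering():
    table = _metric_table({"a": np.zeros(20), "b": np.full(20, 3.0),
                           "c": np.full(20, -3.0)}, seed=3)
    m1 = pairwise_discrimination(table, METRIC_NAMES[:2])
    shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
    m2 = pairwise_discrimination(shuffled, METRIC_NAMES[:2])
    assert m1.lines == m2.lines
    assert np.array_equal(m1.matrix, m2.matrix)


def test_per_time_mode_and_missing_metric():
    table = _metric_table({"a": np.zeros(20), "b": np.full(20, 3.0)}, seed=4)
    m = pairwise_discrimination(table, METRIC_NAMES[:2], per_time=True)
    assert m.pair("a", "b") == 1
    with pytest.raises(ValueError, match="absent"):
        pairwise_discrimination(table.drop(columns=[METRIC_NAMES[0]]),
                                METRIC_NAMES[:2])


def _trend_table(early_vals, late_vals, metric=METRIC_NAMES[0]):
    rows = []
    for t, vals in ((10.0, early_vals), (16.0, early_vals),
                    (120.0, late_vals), (168.0, late_vals)):
        for r, v in enumerate(vals, start=1):
            row = {name: 0.0 for name in METRIC_NAMES}
            row[metric] = v
            row.update(sample_id=f"x_{t}_{r}", cell_line="x", time_h=t, replicate=r)
            rows.append(row)
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + METRIC_NAMES)


def test_trend_profile_percent_change_and_bins():
    table = _trend_table([10.0], [15.0])
    row = trend_profile(table, metric_subset=[METRIC_NAMES[0]]).iloc[0]
    assert row["pct_change"] == pytest.approx(50.0)
    assert row["bin"] == 2  # 50% sits in the second step band (10..50 is one)
    flat = trend_profile(_trend_table([10.0], [10.0]), metric_subset=[METRIC_NAMES[0]])
    assert flat.iloc[0]["pct_change"] == 0.0 and flat.iloc[0]["bin"] == 0
    down = trend_profile(_trend_table([10.0], [1.0]), metric_subset=[METRIC_NAMES[0]])
    assert down.iloc[0]["pct_change"] == pytest.approx(-90.0)
    assert down.iloc[0]["bin"] == -2


def test_trend_profile_zero_early_mean_flagged():
    prof = trend_profile(_trend_table([0.0], [5.0]), metric_subset=[METRIC_NAMES[0]])
    row = prof.iloc[0]
    assert not row["defined"] and np.isnan(row["pct_change"])


def test_trend_profile_missing_time_point_listed():
    table = _trend_table([1.0], [2.0])
    with pytest.raises(ValueError, match="24"):
        trend_profile(table, early_times=(10.0, 24.0))
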