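"""Pairwise cell-line discrimination and temporal trend profiles.

Two cell lines are called distinguishable when, for at least one of the
selected (most influential) metrics, a two-sample Kolmogorov-Smirnov test
rejects equality of the metric's distributions at the chosen significance
level (default 10%) — the per-metric decisions are combined by logical OR.
By default the per-line samples pool all replicates across all time points
(5 replicates x 6 time points = 30 values per metric at the emulated
design), so the comparison sees each line's whole temporal trajectory.

Trend profiles summarise each (line, metric) trajectory by the percent
change from the early-time mean (hours 10 and 16) to the late-time mean
(hours 120 and 168), binned into signed step categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

__all__ = [
    "KSResult",
    "ks_two_sample",
    "DiscriminationMatrix",
    "pairwise_discrimination",
    "metric_samples_from_table",
    "trend_profile",
]


@dataclass
class KSResult:
    statistic: float
    p_value: float
    reject: int  # 1 = distributions differ at the given level


def ks_two_sample(x, y, alpha: float = 0.10) -> KSResult:
    """Two-sample KS test with the asymptotic Kolmogorov p-value.

    D is the supremum over the pooled sample values of the difference of
    the two (right-continuous) empirical CDFs; the p-value evaluates the
    Kolmogorov distribution at ``sqrt(n_x n_y / (n_x + n_y)) * D``.
    ``reject = 1`` iff p < alpha.
    """
    x = np.sort(np.asarray(x, dtype=float).ravel())
    y = np.sort(np.asarray(y, dtype=float).ravel())
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / x.size
    fy = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.abs(fx - fy).max())
    effective = x.size * y.size / (x.size + y.size)
    p = float(kolmogorov(np.sqrt(effective) * d))
    return KSResult(statistic=d, p_value=p, reject=int(p < alpha))


@dataclass
class DiscriminationMatrix:
    """Symmetric 0/1 matrix over cell lines; 1 = distinguishable."""

    lines: list
    matrix: np.ndarray
    alpha: float
    metric_subset: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.lines, columns=self.lines)

    def pair(self, a: str, b: str) -> int:
        return int(self.matrix[self.lines.index(a), self.lines.index(b)])


def metric_samples_from_table(
    metric_table: pd.DataFrame,
    metric_subset: list,
    per_time: bool = False,
) -> dict:
    """Per (line, metric) value arrays from a batch metric table.

    With ``per_time=False`` (default) replicate values are pooled across
    all time points; with ``per_time=True`` the arrays are keyed
    (line, metric, time_h) instead.
    """
    missing = [m for m in metric_subset if m not in metric_table.columns]
    if missing:
        raise ValueError(f"metrics absent from table: {missing}")
    samples: dict = {}
    if per_time:
        for (line, t), sub in metric_table.groupby(["cell_line", "time_h"]):
            for m in metric_subset:
                samples[(str(line), m, float(t))] = sub[m].to_numpy(dtype=float)
    else:
        for line, sub in metric_table.groupby("cell_line"):
            for m in metric_subset:
                samples[(str(line), m)] = sub[m].to_numpy(dtype=float)
    return samples


def pairwise_discrimination(
    metric_table: pd.DataFrame,
    metric_subset: list,
    alpha: float = 0.10,
    per_time: bool = False,
    bonferroni: bool = False,
) -> DiscriminationMatrix:
    """OR-combined KS discrimination over all unordered line pairs.

    For each pair, one KS test per metric in ``metric_subset`` is run on
    the pooled values (or per time point with ``per_time=True``, ORing over
    times as well); the pair is marked distinguishable if any test rejects.
    ``bonferroni=True`` divides alpha by the number of tests per pair
    (off by default: the plain OR at the nominal level is the method's
    stated combination rule).
    """
    lines = sorted(metric_table["cell_line"].astype(str).unique())
    samples = metric_samples_from_table(metric_table, metric_subset, per_time=per_time)
    times = sorted(metric_table["time_h"].unique()) if per_time else [None]
    n_tests = len(metric_subset) * len(times)
    level = alpha / n_tests if bonferroni else alpha
    mat = np.zeros((len(lines), len(lines)), dtype=int)
    for i, a in enumerate(lines):
        for j in range(i + 1, len(lines)):
            b = lines[j]
            distinguishable = 0
            for m in metric_subset:
                for t in times:
                    key_a = (a, m) if t is None else (a, m, float(t))
                    key_b = (b, m) if t is None else (b, m, float(t))
                    if ks_two_sample(samples[key_a], samples[key_b], level).reject:
                        distinguishable = 1
                        break
                if distinguishable:
                    break
            mat[i, j] = mat[j, i] = distinguishable
    return DiscriminationMatrix(lines=lines, matrix=mat, alpha=alpha, metric_subset=list(metric_subset))


#: Default |percent change| bin edges: below 10% is flat, then one, two or
#: three steps at 50% and 150%.
DEFAULT_BIN_EDGES = (10.0, 50.0, 150.0)


def trend_profile(
    metric_table: pd.DataFrame,
    metric_subset: list | None = None,
    early_times=(10.0, 16.0),
    late_times=(120.0, 168.0),
    bin_edges=DEFAULT_BIN_EDGES,
) -> pd.DataFrame:
    """Percent change of each metric per line from early to late times.

    Returns a frame with columns (cell_line, metric, early, late,
    pct_change, bin, defined).  ``bin`` is a signed integer in -3..3 whose
    magnitude counts the bin edges below |pct_change| (0 = flat); an early
    mean of exactly 0 makes the percent change undefined and is flagged.
    """
    if not len(early_times) or not len(late_times):
        raise ValueError("early/late time sets must be non-empty")
    have = set(metric_table["time_h"].unique())
    missing = [t for t in (*early_times, *late_times) if t not in have]
    if missing:
        raise ValueError(f"time points absent from table: {missing}")
    metrics = metric_subset or [
        c for c in metric_table.columns
        if c not in ("sample_id", "cell_line", "time_h", "replicate")
    ]
    edges = np.asarray(bin_edges, dtype=float)
    rows = []
    for line, sub in metric_table.groupby("cell_line", sort=True):
        early = sub[sub["time_h"].isin(early_times)]
        late = sub[sub["time_h"].isin(late_times)]
        for m in metrics:
            e = float(early[m].mean())
            l = float(late[m].mean())
            if e == 0.0:
                rows.append(
                    dict(cell_line=str(line), metric=m, early=e, late=l,
                         pct_change=np.nan, bin=np.nan, defined=False)
                )
                continue
            pct = 100.0 * (l - e) / abs(e)
            magnitude = int(np.searchsorted(edges, abs(pct), side="right"))
            rows.append(
                dict(cell_line=str(line), metric=m, early=e, late=l,
                     pct_change=pct, bin=int(np.sign(pct)) * magnitude, defined=True)
            )
    return pd.DataFrame(rows)
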