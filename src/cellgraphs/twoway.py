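"""Two-way (condition x feature) SVD-based feature influence.

The two-mode analog of the tensor analysis: per-condition metric means form
a small matrix (e.g. 6 tumour types x 20 metrics), which is autoscaled and
decomposed by SVD; a feature's influence is the summed magnitude of its
loadings over the leading components, weighted by the singular values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES

__all__ = ["TwoWayMatrix", "build_twoway", "svd_influence", "TwoWayInfluence"]


@dataclass
class TwoWayMatrix:
    """Complete condition x feature matrix with labels."""

    entries: np.ndarray
    conditions: list
    features: list

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (len(self.conditions), len(self.features)):
            raise ValueError("entries shape does not match labels")
        if np.isnan(self.entries).any():
            raise ValueError("two-way matrix has missing cells")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.conditions, columns=self.features)


@dataclass
class TwoWayInfluence:
    features: list
    influence: np.ndarray
    rank: np.ndarray  # 1 = most influential
    n_components: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature": self.features, "influence": self.influence, "rank": self.rank}
        ).sort_values("rank", ignore_index=True)


def build_twoway(metric_table: pd.DataFrame, condition_key: str = "cell_line") -> TwoWayMatrix:
    """Per-condition mean of each metric over its samples."""
    features = [m for m in METRIC_NAMES if m in metric_table.columns]
    if not features:
        raise ValueError("metric_table contains no metric columns")
    if metric_table.empty:
        raise ValueError("metric_table is empty")
    means = metric_table.groupby(condition_key, sort=True)[features].mean()
    return TwoWayMatrix(
        entries=means.to_numpy(),
        conditions=[str(c) for c in means.index],
        features=features,
    )


def svd_influence(
    matrix: TwoWayMatrix,
    var_threshold: float = 0.95,
    n_components: int | None = None,
    score_mode: str = "loadings_scaled",
    on_degenerate: str = "error",
) -> TwoWayInfluence:
    """Rank features by summed leading-component loading magnitude.

    The matrix is autoscaled (columns centred over conditions and divided
    by their n-1 standard deviation), decomposed as ``M = U S V^T``, and
    the number of components K is the smallest count whose cumulative
    squared singular values reach ``var_threshold`` (or ``n_components``
    if given explicitly).  Influence of feature m is
    ``sum_{k<=K} |V[m, k] * s_k|`` (``score_mode="loadings_scaled"``,
    default) or the unweighted ``sum_{k<=K} |V[m, k]|``
    (``score_mode="loadings"``).  Sign indeterminacy is resolved by making
    each right singular vector's largest-magnitude entry positive.

    A zero-variance feature column cannot be autoscaled: with
    ``on_degenerate="error"`` (default) it raises naming the feature, with
    ``"drop"`` the column is excluded from the analysis (and the result).
    """
    m = matrix.entries
    features = list(matrix.features)
    if score_mode not in ("loadings_scaled", "loadings"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    if on_degenerate not in ("error", "drop"):
        raise ValueError(f"unknown on_degenerate policy {on_degenerate!r}")
    if m.shape[0] < 2:
        raise ValueError("need at least 2 conditions and 2 features")
    sd = m.std(axis=0, ddof=1)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [features[i] for i in dead]
        if on_degenerate == "error":
            raise ValueError(f"zero-variance feature column(s): {names}")
        keep = np.flatnonzero(sd > 0)
        m = m[:, keep]
        sd = sd[keep]
        features = [features[i] for i in keep]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 conditions and 2 features")
    scaled = (m - m.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(scaled, full_matrices=False)
    v = vt.T
    flip = np.sign(v[np.argmax(np.abs(v), axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    v = v * flip
    if n_components is None:
        energy = s**2
        cum = np.cumsum(energy) / energy.sum()
        k = int(np.searchsorted(cum, var_threshold - 1e-12) + 1)
    else:
        k = int(n_components)
        if not (1 <= k <= len(s)):
            raise ValueError(f"n_components must be in [1, {len(s)}]")
    if score_mode == "loadings_scaled":
        infl = np.abs(v[:, :k] * s[:k]).sum(axis=1)
    else:
        infl = np.abs(v[:, :k]).sum(axis=1)
    order = np.argsort(-infl, kind="stable")
    rank = np.empty(len(infl), dtype=int)
    rank[order] = np.arange(1, len(infl) + 1)
    return TwoWayInfluence(
        features=features, influence=infl, rank=rank, n_components=k
    )
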