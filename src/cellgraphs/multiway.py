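"""Three-way analysis of the feature x time x cell-line metric tensor.

The metric table is organised into a third-order tensor T whose entry
``T[i, j, k]`` is metric *i* at time point *j* for cell line *k*
(replicates averaged).  Before model fitting the tensor is normalised by
sequential centering across the time and cell-line modes and autoscaling
within the feature mode.  Two multilinear models are provided:

* **Tucker3** — ``T ~ G x1 A x2 B x3 C`` with column-orthonormal factor
  matrices A (I x P), B (J x Q), C (K x R) and a dense P x Q x R core G,
  fitted by higher-order orthogonal iteration (HOOI) from an HOSVD start.
* **PARAFAC/CANDECOMP** — ``T ~ sum_r w_r a_r o b_r o c_r`` (o = outer
  product), fitted by alternating least squares with multi-start.

Component counts default to the smallest numbers capturing at least 95% of
the variance of each mode's unfolding.  Feature influence is ranked by
Hotelling's T^2 in factor-score space together with each feature's sum of
squared residuals, combined by rank-sum; the top-k set (default 5) is the
package's analog of "the most significant metrics".
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTensor",
    "NormalizationRecord",
    "TuckerModel",
    "ParafacModel",
    "InfluenceScores",
    "assemble_tensor",
    "normalize_tensor",
    "denormalize_tensor",
    "select_components",
    "select_dims_diffit",
    "tucker_fit_grid",
    "fit_tucker3",
    "fit_parafac",
    "influence_scores",
    "unfold",
]


@dataclass
class FeatureTensor:
    """3-mode array (feature x time x cell line) with mode labels."""

    entries: np.ndarray
    feature_names: list
    time_points: list
    cell_lines: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 3:
            raise ValueError("entries must be a 3-mode array")
        expected = (len(self.feature_names), len(self.time_points), len(self.cell_lines))
        if self.entries.shape != expected:
            raise ValueError(
                f"entries shape {self.entries.shape} does not match labels {expected}"
            )
        if np.isnan(self.entries).any():
            raise ValueError("tensor has missing entries")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.entries.shape

    def to_long_frame(self) -> pd.DataFrame:
        i, j, k = np.indices(self.shape)
        return pd.DataFrame(
            {
                "feature": np.asarray(self.feature_names)[i.ravel()],
                "time_h": np.asarray(self.time_points)[j.ravel()],
                "cell_line": np.asarray(self.cell_lines)[k.ravel()],
                "value": self.entries.ravel(),
            }
        )

    @classmethod
    def from_long_frame(cls, df: pd.DataFrame) -> "FeatureTensor":
        features = list(dict.fromkeys(df["feature"]))
        times = sorted(df["time_h"].unique())
        lines = sorted(df["cell_line"].unique())
        pivot = df.set_index(["feature", "time_h", "cell_line"])["value"]
        entries = np.full((len(features), len(times), len(lines)), np.nan)
        for (f, t, l), v in pivot.items():
            entries[features.index(f), times.index(t), lines.index(l)] = v
        return cls(entries, features, [float(t) for t in times], [str(l) for l in lines])


@dataclass
class NormalizationRecord:
    """Everything needed to undo centering/scaling exactly."""

    time_means: np.ndarray  # (I, K): mean over j removed per (i, k)
    line_means: np.ndarray  # (I, J): mean over k removed per (i, j)
    feature_sds: np.ndarray  # (I,): per-feature slice sd divided out


def assemble_tensor(metric_table: pd.DataFrame) -> FeatureTensor:
    """Average replicates into the feature x time x line tensor.

    ``metric_table`` is the batch output of :func:`cellgraphs.metrics
    .metrics_table` (one row per sample).  Times sort ascending, cell lines
    lexicographically, features in the fixed metric order.  A missing
    (time, line) design cell is an error listing the holes.
    """
    features = [m for m in METRIC_NAMES if m in metric_table.columns]
    if not features:
        raise ValueError("metric_table contains no metric columns")
    times = sorted(metric_table["time_h"].unique())
    lines = sorted(metric_table["cell_line"].unique(), key=str)
    have = set(zip(metric_table["time_h"], metric_table["cell_line"]))
    holes = [(t, l) for t in times for l in lines if (t, l) not in have]
    if holes:
        raise ValueError(f"incomplete design; missing (time_h, cell_line) cells: {holes}")
    means = metric_table.groupby(["time_h", "cell_line"], sort=True)[features].mean()
    entries = np.empty((len(features), len(times), len(lines)))
    for j, t in enumerate(times):
        for k, l in enumerate(lines):
            entries[:, j, k] = means.loc[(t, l)].to_numpy()
    return FeatureTensor(entries, list(features), [float(t) for t in times], [str(l) for l in lines])


def normalize_tensor(tensor: FeatureTensor) -> tuple[FeatureTensor, NormalizationRecord]:
    """Sequential double centering, then feature-mode autoscaling.

    Step 1 removes, for each (feature, line) fibre, its mean over time;
    step 2 removes, for each (feature, time) fibre, its mean over lines;
    step 3 divides each feature's J x K slice by that slice's standard
    deviation (n-1 over the JK entries).  A zero-variance feature slice is
    a degenerate feature and raises.
    """
    x = tensor.entries.astype(float).copy()
    time_means = x.mean(axis=1)  # (I, K)
    x -= time_means[:, None, :]
    line_means = x.mean(axis=2)  # (I, J)
    x -= line_means[:, :, None]
    sds = x.std(axis=(1, 2), ddof=1)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        names = [tensor.feature_names[i] for i in dead]
        raise ValueError(f"zero-variance feature slice(s) after centering: {names}")
    x /= sds[:, None, None]
    record = NormalizationRecord(time_means=time_means, line_means=line_means, feature_sds=sds)
    normalized = FeatureTensor(
        x, tensor.feature_names, tensor.time_points, tensor.cell_lines,
        meta=dict(tensor.meta, normalized=True),
    )
    return normalized, record


def denormalize_tensor(tensor: FeatureTensor, record: NormalizationRecord) -> FeatureTensor:
    """Exact inverse of :func:`normalize_tensor`."""
    x = tensor.entries * record.feature_sds[:, None, None]
    x = x + record.line_means[:, :, None]
    x = x + record.time_means[:, None, :]
    meta = dict(tensor.meta)
    meta.pop("normalized", None)
    return FeatureTensor(x, tensor.feature_names, tensor.time_points, tensor.cell_lines, meta=meta)


def unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n matricization: mode ``mode`` becomes the rows."""
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _fold(mat: np.ndarray, mode: int, shape: tuple) -> np.ndarray:
    full = [shape[mode]] + [s for i, s in enumerate(shape) if i != mode]
    return np.moveaxis(mat.reshape(full), 0, mode)


def _multi_mode_dot(x: np.ndarray, mats: list, transpose: bool = False) -> np.ndarray:
    """Contract x with a matrix per mode (skip None entries)."""
    out = x
    for mode, m in enumerate(mats):
        if m is None:
            continue
        mm = m.T if transpose else m
        out = _fold(mm @ unfold(out, mode), mode, _shape_after(out.shape, mode, mm.shape[0]))
    return out


def _shape_after(shape, mode, new):
    s = list(shape)
    s[mode] = new
    return tuple(s)


def select_components(tensor: FeatureTensor, var_threshold: float = 0.95) -> tuple[int, int, int]:
    """Smallest per-mode component counts capturing the variance threshold.

    Each mode's unfolding is decomposed by SVD and the count is the
    smallest number of leading components whose cumulative squared singular
    values reach ``var_threshold`` of the total.
    """
    if not (0 < var_threshold <= 1):
        raise ValueError("var_threshold must be in (0, 1]")
    dims = []
    for mode in range(3):
        s = np.linalg.svd(unfold(tensor.entries, mode), compute_uv=False)
        energy = s**2
        cum = np.cumsum(energy) / energy.sum()
        dims.append(int(np.searchsorted(cum, var_threshold - 1e-12) + 1))
    return tuple(dims)


def _admissible_dims(shape) -> dict[int, list]:
    """Admissible Tucker dims grouped by total component count.

    Each mode's component count is bounded by the mode size and by the
    product of the other two (the multilinear-rank constraint)."""
    candidates: dict[int, list] = {}
    for p in range(1, shape[0] + 1):
        for q in range(1, shape[1] + 1):
            for r in range(1, shape[2] + 1):
                if p > q * r or q > p * r or r > p * q:
                    continue
                candidates.setdefault(p + q + r, []).append((p, q, r))
    return candidates


def _expand_orthonormal(basis: np.ndarray) -> np.ndarray:
    """Append one orthonormal column (deterministic complement direction)."""
    n, k = basis.shape
    for i in range(n):
        v = np.zeros(n)
        v[i] = 1.0
        v -= basis @ (basis.T @ v)
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            return np.hstack([basis, (v / norm)[:, None]])
    raise RuntimeError("no orthonormal complement found")  # k = n, unreachable


def tucker_fit_grid(
    tensor: FeatureTensor,
    max_total: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> dict[tuple[int, int, int], float]:
    """Tucker3 fit percentage over the whole admissible dims lattice.

    Fits are computed in increasing total component count; each fit is
    warm-started both from HOSVD and from every already-solved sub-model
    expanded by one orthonormal column.  An expanded init reproduces its
    parent's fit exactly and HOOI never decreases it, so the returned fits
    are monotone non-decreasing along the lattice by construction.
    """
    x = tensor.entries
    candidates = _admissible_dims(tensor.shape)
    totals = sorted(candidates)
    if max_total is not None:
        totals = [s for s in totals if s <= max_total] or totals[:1]
    fits: dict[tuple, float] = {}
    factors_of: dict[tuple, list] = {}
    for s in totals:
        for dims in candidates[s]:
            inits = [[_truncated_basis(x, mode, d) for mode, d in enumerate(dims)]]
            for mode in range(3):
                parent = list(dims)
                parent[mode] -= 1
                parent = tuple(parent)
                if parent in factors_of:
                    init = [f.copy() for f in factors_of[parent]]
                    init[mode] = _expand_orthonormal(init[mode])
                    inits.append(init)
            best_fit, best_factors = -np.inf, None
            for init in inits:
                model = _hooi_from(x, init, dims, tol=tol, max_iter=max_iter)
                if model[1] > best_fit:
                    best_factors, best_fit = model
            fits[dims] = best_fit
            factors_of[dims] = best_factors
    return fits


def select_dims_diffit(
    tensor: FeatureTensor,
    max_total: int | None = None,
    min_gain_pct: float = 0.5,
) -> tuple[int, int, int]:
    """Parsimonious Tucker dims by the DIFFIT (difference-in-fit) heuristic.

    The Tucker3 fit percentage is evaluated over the admissible dims grid
    (see :func:`tucker_fit_grid`); per total component count s = P+Q+R the
    best fit is kept, and the selected s* maximises the salience ratio
    dif(s)/dif(s+1) among totals whose fit gain dif(s) exceeds
    ``min_gain_pct`` percentage points.  This locates the knee where added
    components stop capturing systematic structure — unlike a raw variance
    threshold, it does not saturate when many features are weakly
    structured.
    """
    grid = tucker_fit_grid(tensor, max_total=max_total)
    fits: dict[int, float] = {}
    best: dict[int, tuple] = {}
    for dims, fit in grid.items():
        s = sum(dims)
        if fit > fits.get(s, -np.inf):
            fits[s] = fit
            best[s] = dims
    totals = sorted(fits)
    difs = {s: fits[s] - fits.get(s - 1, 0.0) for s in totals}
    informative = [s for s in totals[1:-1] if difs[s] > min_gain_pct]
    if not informative:
        return best[totals[0]]
    salience = {s: difs[s] / max(difs.get(s + 1, 0.0), 1e-9) for s in informative}
    return best[max(salience, key=salience.get)]


@dataclass
class TuckerModel:
    A: np.ndarray  # I x P, columnwise orthonormal
    B: np.ndarray  # J x Q
    C: np.ndarray  # K x R
    core: np.ndarray  # P x Q x R
    residual: np.ndarray  # I x J x K
    explained_variation_pct: float
    tensor: FeatureTensor  # the (normalized) tensor that was fitted

    @property
    def feature_factors(self) -> np.ndarray:
        return self.A

    def reconstruction(self) -> np.ndarray:
        return _multi_mode_dot(self.core, [self.A, self.B, self.C])


@dataclass
class ParafacModel:
    A: np.ndarray  # I x R, unit-norm columns
    B: np.ndarray  # J x R
    C: np.ndarray  # K x R
    weights: np.ndarray  # (R,), non-negative, descending
    residual: np.ndarray
    explained_variation_pct: float
    tensor: FeatureTensor

    @property
    def feature_factors(self) -> np.ndarray:
        """Feature-mode scores with component weights absorbed."""
        return self.A * self.weights

    def reconstruction(self) -> np.ndarray:
        return np.einsum("r,ir,jr,kr->ijk", self.weights, self.A, self.B, self.C)


def _truncated_basis(x: np.ndarray, mode: int, rank: int) -> np.ndarray:
    u, _, _ = np.linalg.svd(unfold(x, mode), full_matrices=False)
    return u[:, :rank]


def _hooi_from(x, factors, dims, tol, max_iter):
    """Run HOOI from the given factor init; returns (factors, fit ratio%)."""
    norm_x = np.linalg.norm(x)
    prev_fit = -np.inf
    fit = 0.0
    for _ in range(max_iter):
        for mode in range(3):
            others = [f if m != mode else None for m, f in enumerate(factors)]
            y = _multi_mode_dot(x, others, transpose=True)
            u, _, _ = np.linalg.svd(unfold(y, mode), full_matrices=False)
            factors[mode] = u[:, : dims[mode]]
        core = _multi_mode_dot(x, factors, transpose=True)
        ratio = np.linalg.norm(core) / norm_x if norm_x > 0 else 1.0
        fit = 100.0 * ratio**2
        if abs(ratio - prev_fit) < tol * max(prev_fit, 1e-300):
            break
        prev_fit = ratio
    return factors, fit


def fit_tucker3(
    tensor: FeatureTensor,
    dims: tuple[int, int, int],
    tol: float = 1e-8,
    max_iter: int = 500,
    n_starts: int = 2,
    seed: int = 0,
) -> TuckerModel:
    """Fit a (P, Q, R)-component Tucker3 model by HOOI.

    Initialised by truncated mode-wise SVD (HOSVD) plus ``n_starts`` random
    orthonormal restarts (HOOI can hit local optima); each run iterates
    until the relative change in explained fit drops below ``tol`` and the
    best fit is kept.  The residual satisfies reconstruction + residual ==
    tensor to numerical tolerance.
    """
    x = tensor.entries
    shape = x.shape
    dims = tuple(int(d) for d in dims)
    if any(d < 1 for d in dims) or any(d > s for d, s in zip(dims, shape)):
        raise ValueError(f"dims {dims} invalid for tensor of shape {shape}")
    norm_x = np.linalg.norm(x)
    rng = np.random.default_rng(seed)
    inits = [[_truncated_basis(x, mode, d) for mode, d in enumerate(dims)]]
    for _ in range(int(n_starts)):
        inits.append([
            np.linalg.qr(rng.standard_normal((s, d)))[0]
            for s, d in zip(shape, dims)
        ])
    best_factors, best_fit = None, -np.inf
    for init in inits:
        factors, fit = _hooi_from(x, init, dims, tol=tol, max_iter=max_iter)
        if fit > best_fit:
            best_factors, best_fit = factors, fit
    core = _multi_mode_dot(x, best_factors, transpose=True)
    recon = _multi_mode_dot(core, best_factors)
    residual = x - recon
    explained = 100.0 * (1.0 - (np.linalg.norm(residual) / norm_x) ** 2) if norm_x > 0 else 100.0
    return TuckerModel(
        A=best_factors[0], B=best_factors[1], C=best_factors[2], core=core,
        residual=residual, explained_variation_pct=float(explained), tensor=tensor,
    )


def _khatri_rao(b: np.ndarray, c: np.ndarray) -> np.ndarray:
    r = b.shape[1]
    return (b[:, None, :] * c[None, :, :]).reshape(-1, r)


def _parafac_recon(a, b, c):
    return np.einsum("ir,jr,kr->ijk", a, b, c)


def congruence(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Columnwise cosine (Tucker congruence) matrix between factor sets."""
    un = u / np.linalg.norm(u, axis=0, keepdims=True)
    vn = v / np.linalg.norm(v, axis=0, keepdims=True)
    return un.T @ vn


def fit_parafac(
    tensor: FeatureTensor,
    n_components: int,
    n_starts: int = 4,
    seed=0,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> ParafacModel:
    """Fit an R-component PARAFAC model by multi-start ALS.

    ``n_starts`` random initialisations plus one SVD-based one are run to
    convergence and the best fit kept.  Components are normalised to unit
    factor columns with non-negative weights, sorted by decreasing weight;
    a high two-factor congruence between distinct components (a degeneracy
    indicator) is logged.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x = tensor.entries
    shape = x.shape
    r = int(n_components)
    rng = np.random.default_rng(seed)
    norm_x = np.linalg.norm(x)

    def svd_init():
        mats = []
        for mode in range(3):
            u, _, _ = np.linalg.svd(unfold(x, mode), full_matrices=False)
            m = u[:, :r]
            if m.shape[1] < r:  # pad rank-deficient modes with random columns
                pad = rng.standard_normal((shape[mode], r - m.shape[1]))
                m = np.hstack([m, pad])
            mats.append(m)
        return mats

    def als(factors):
        a, b, c = (f.copy() for f in factors)
        prev_err = np.inf
        for _ in range(max_iter):
            for mode, (lhs, rhs1, rhs2) in enumerate(
                [(0, 1, 2), (1, 0, 2), (2, 0, 1)]
            ):
                mats = [a, b, c]
                f1, f2 = mats[rhs1], mats[rhs2]
                kr = _khatri_rao(f1, f2)
                gram = (f1.T @ f1) * (f2.T @ f2)
                sol = np.linalg.solve(
                    gram + 1e-12 * np.eye(r), (unfold(x, lhs) @ kr).T
                ).T
                if lhs == 0:
                    a = sol
                elif lhs == 1:
                    b = sol
                else:
                    c = sol
            err = np.linalg.norm(x - _parafac_recon(a, b, c))
            rel = err / norm_x if norm_x > 0 else 0.0
            if abs(prev_err - rel) < tol:
                prev_err = rel
                break
            prev_err = rel
        return a, b, c, prev_err

    inits = [svd_init()] + [
        [rng.standard_normal((s, r)) for s in shape] for _ in range(int(n_starts))
    ]
    best = None
    for init in inits:
        a, b, c, rel_err = als(init)
        if best is None or rel_err < best[-1]:
            best = (a, b, c, rel_err)
    a, b, c, _ = best

    # normalize columns, absorb scale into non-negative weights, sort, fix signs
    na = np.linalg.norm(a, axis=0)
    nb = np.linalg.norm(b, axis=0)
    nc = np.linalg.norm(c, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    nc[nc == 0] = 1.0
    a, b, c = a / na, b / nb, c / nc
    weights = na * nb * nc
    for mats in (b, c):  # deterministic signs: dominant entry positive in B, C
        idx = np.argmax(np.abs(mats), axis=0)
        signs = np.sign(mats[idx, np.arange(r)])
        signs[signs == 0] = 1.0
        mats *= signs
        a *= signs
    # weights are products of norms, hence >= 0; with B/C signs pinned the
    # sign of each A column is determined by the data itself
    order = np.argsort(-weights)
    a, b, c, weights = a[:, order], b[:, order], c[:, order], weights[order]
    recon = np.einsum("r,ir,jr,kr->ijk", weights, a, b, c)
    residual = x - recon
    explained = 100.0 * (1.0 - (np.linalg.norm(residual) / norm_x) ** 2) if norm_x > 0 else 100.0
    if r > 1:
        cong = np.abs(congruence(a, a) * congruence(b, b) * congruence(c, c))
        np.fill_diagonal(cong, 0.0)
        worst = cong.max()
        if worst > 0.85:
            logger.info("PARAFAC two-factor congruence %.3f suggests degeneracy", worst)
    return ParafacModel(
        A=a, B=b, C=c, weights=weights, residual=residual,
        explained_variation_pct=float(explained), tensor=tensor,
    )


@dataclass
class InfluenceScores:
    """Per-feature influence summary from a fitted multiway model."""

    feature_names: list
    hotelling_t2: np.ndarray
    ssr: np.ndarray
    combined_rank: np.ndarray  # rank-sum; smaller = more influential
    selected: list  # top-k feature names
    top_k: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "hotelling_t2": self.hotelling_t2,
                "ssr": self.ssr,
                "combined_rank": self.combined_rank,
                "selected": [f in self.selected for f in self.feature_names],
            }
        )


def _descending_ranks(values: np.ndarray) -> np.ndarray:
    """Rank 1 = largest value; ties share the smaller rank via stable sort."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def influence_scores(
    model: TuckerModel | ParafacModel,
    top_k: int = 5,
    combine: str = "t2",
) -> InfluenceScores:
    """Hotelling's T^2 and residual-based influence of each feature.

    T^2 of feature i is the variance-normalised squared deviation of its
    feature-mode factor scores from the column means (a diagonal-covariance
    Mahalanobis distance in score space); SSR is the sum of squared
    residuals over the feature's J x K slice.

    With ``combine="t2"`` (default) features are ranked by descending T^2
    — after feature autoscaling every slice carries equal total variance,
    so T^2 in a parsimonious model directly measures how much *systematic*
    time-by-line structure a feature carries, while SSR is its complement
    and is reported as a diagnostic.  ``combine="ranksum"`` instead orders
    by the sum of descending T^2 and SSR ranks (ties broken by T^2, then
    feature index).
    """
    scores = model.feature_factors
    n_features = scores.shape[0]
    if n_features < 2:
        raise ValueError("influence requires at least 2 features")
    if combine not in ("t2", "ranksum"):
        raise ValueError(f"unknown combine rule {combine!r}")
    centred = scores - scores.mean(axis=0)
    var = centred.var(axis=0, ddof=1)
    safe = np.where(var > 0, var, np.inf)
    t2 = (centred**2 / safe).sum(axis=1)
    ssr = (model.residual**2).sum(axis=(1, 2))
    if combine == "t2":
        rank_sum = _descending_ranks(t2)
    else:
        rank_sum = _descending_ranks(t2) + _descending_ranks(ssr)
    order = sorted(
        range(n_features), key=lambda i: (rank_sum[i], -t2[i], i)
    )
    names = list(model.tensor.feature_names)
    selected = [names[i] for i in order[:top_k]]
    return InfluenceScores(
        feature_names=names,
        hotelling_t2=t2,
        ssr=ssr,
        combined_rank=rank_sum,
        selected=selected,
        top_k=top_k,
    )
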