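"""The 20 structural cell-graph metrics.

The metric vector characterises a cell-graph's architecture in three
families — compactness (degree, eccentricity, path-length, central/isolated
points), clustering (clustering coefficients, connected components), and
spatial uniformity (edge-length distribution moments).  The fixed index
order is::

     1 average_degree              11 n_connected_components
     2 clustering_coefficient_c    12 avg_component_size
     3 clustering_coefficient_d    13 pct_isolated_points
     4 clustering_coefficient_e    14 pct_end_points
     5 average_eccentricity        15 n_central_points
     6 diameter                    16 pct_central_points
     7 radius                      17 mean_edge_length
     8 average_path_length         18 std_edge_length
     9 hop_plot_exponent           19 skewness_edge_length
    10 gcc_ratio                   20 kurtosis_edge_length

Hydrogel graphs are usually disconnected, so hop-count metrics
(eccentricity, path length, hop plot) are evaluated within connected
components over non-isolated nodes, which keeps every quantity finite.
Degenerate cases (edgeless graphs, zero-variance edge lengths) yield 0
with a warning rather than NaN, so every graph is scorable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

from .graphs import CellGraph

__all__ = [
    "METRIC_NAMES",
    "MetricVector",
    "average_degree",
    "clustering_coefficients",
    "eccentricity_metrics",
    "average_path_length",
    "hop_plot_exponent",
    "component_metrics",
    "point_percentages",
    "edge_length_stats",
    "compute_metric_vector",
    "metrics_table",
]

METRIC_NAMES = [
    "average_degree",
    "clustering_coefficient_c",
    "clustering_coefficient_d",
    "clustering_coefficient_e",
    "average_eccentricity",
    "diameter",
    "radius",
    "average_path_length",
    "hop_plot_exponent",
    "gcc_ratio",
    "n_connected_components",
    "avg_component_size",
    "pct_isolated_points",
    "pct_end_points",
    "n_central_points",
    "pct_central_points",
    "mean_edge_length",
    "std_edge_length",
    "skewness_edge_length",
    "kurtosis_edge_length",
]

LABEL_COLUMNS = ["sample_id", "cell_line", "time_h", "replicate"]


@dataclass
class MetricVector:
    """Ordered length-20 metric vector for one sample."""

    values: np.ndarray
    sample_id: str = ""
    cell_line: str = ""
    time_h: float = float("nan")
    replicate: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(METRIC_NAMES),):
            raise ValueError(f"metric vector must have length {len(METRIC_NAMES)}")

    def as_dict(self) -> dict:
        return dict(zip(METRIC_NAMES, self.values))

    def to_row(self) -> dict:
        row = {
            "sample_id": self.sample_id,
            "cell_line": self.cell_line,
            "time_h": self.time_h,
            "replicate": self.replicate,
        }
        row.update(self.as_dict())
        return row


def _require_nonempty(g: CellGraph) -> None:
    if g.n_vertices == 0:
        raise ValueError("metric undefined on an empty graph")


def average_degree(g: CellGraph) -> float:
    """Edges per node: 2|E| / |V|."""
    _require_nonempty(g)
    return 2.0 * g.n_edges / g.n_vertices


def _sparse_adjacency(g: CellGraph) -> csr_matrix:
    n = g.n_vertices
    data = np.ones(2 * g.n_edges)
    rows = np.concatenate([g.edges[:, 0], g.edges[:, 1]])
    cols = np.concatenate([g.edges[:, 1], g.edges[:, 0]])
    return csr_matrix((data, (rows, cols)), shape=(n, n))


def _edges_among_neighbours(g: CellGraph) -> np.ndarray:
    """Per node, the number of edges among its neighbours (= triangles
    through the node), via the diagonal of A^3 in sparse arithmetic."""
    if g.n_edges == 0:
        return np.zeros(g.n_vertices)
    a = _sparse_adjacency(g)
    return np.asarray((a @ a).multiply(a).sum(axis=1)).ravel() / 2.0


def clustering_coefficients(g: CellGraph) -> dict:
    """The three clustering coefficients C, D, E.

    Per node v with degree k and e_v edges among its neighbours:
    ``C_v = e_v / C(k,2)`` (0 when k < 2),
    ``D_v = (k + e_v) / C(k+1,2)`` (0 when k = 0, counting the node itself
    and its spokes), and E averages C_v over non-isolated nodes only.
    """
    _require_nonempty(g)
    deg = g.degrees().astype(float)
    e_v = _edges_among_neighbours(g)
    c_v = np.zeros(g.n_vertices)
    k2 = deg >= 2
    c_v[k2] = e_v[k2] / (deg[k2] * (deg[k2] - 1) / 2.0)
    d_v = np.zeros(g.n_vertices)
    k1 = deg >= 1
    d_v[k1] = (deg[k1] + e_v[k1]) / ((deg[k1] + 1) * deg[k1] / 2.0)
    return {
        "clustering_coefficient_c": float(c_v.mean()),
        "clustering_coefficient_d": float(d_v.mean()),
        "clustering_coefficient_e": float(c_v[k1].mean()) if k1.any() else 0.0,
    }


def _hop_distance_matrix(g: CellGraph) -> np.ndarray:
    """All-pairs hop distances (inf across components)."""
    n = g.n_vertices
    if g.n_edges == 0:
        d = np.full((n, n), np.inf)
        np.fill_diagonal(d, 0.0)
        return d
    return shortest_path(_sparse_adjacency(g), method="D", unweighted=True)


def eccentricity_metrics(g: CellGraph, hop: np.ndarray | None = None) -> dict:
    """Eccentricity summary over non-isolated nodes, per component.

    The eccentricity of a node is its maximum hop distance to any node
    *reachable from it*.  Central points are the considered nodes whose
    eccentricity equals the graph radius; their percentage is taken over
    all nodes (consistent with the isolated/end-point percentages).
    All-isolated graphs yield zeros, with a warning.
    """
    _require_nonempty(g)
    deg = g.degrees()
    considered = deg >= 1
    if not considered.any():
        warnings.warn("all nodes isolated: eccentricity metrics set to 0")
        return {
            "average_eccentricity": 0.0,
            "diameter": 0.0,
            "radius": 0.0,
            "n_central_points": 0.0,
            "pct_central_points": 0.0,
        }
    hop = _hop_distance_matrix(g) if hop is None else hop
    sub = hop[np.ix_(considered, considered)]
    finite = np.where(np.isfinite(sub), sub, -np.inf)
    ecc = finite.max(axis=1)
    radius = float(ecc.min())
    return {
        "average_eccentricity": float(ecc.mean()),
        "diameter": float(ecc.max()),
        "radius": radius,
        "n_central_points": float(np.sum(ecc == radius)),
        "pct_central_points": 100.0 * float(np.sum(ecc == radius)) / g.n_vertices,
    }


def average_path_length(g: CellGraph, hop: np.ndarray | None = None) -> float:
    """Mean hop distance over connected (same-component) distinct pairs."""
    _require_nonempty(g)
    if g.n_edges == 0:
        warnings.warn("no connected pair: average path length set to 0")
        return 0.0
    hop = _hop_distance_matrix(g) if hop is None else hop
    iu = np.triu_indices(g.n_vertices, k=1)
    d = hop[iu]
    d = d[np.isfinite(d)]
    return float(d.mean())


def hop_plot_exponent(g: CellGraph, hop: np.ndarray | None = None) -> float:
    """Log-log slope of N(h), the number of pairs within h hops.

    N(h) is accumulated for h = 1..diameter and fitted by ordinary least
    squares in (log h, log N).  Graphs of diameter <= 1 (or without edges)
    have no slope to fit and yield 0 with a warning.
    """
    _require_nonempty(g)
    if g.n_edges == 0:
        warnings.warn("no edges: hop plot exponent set to 0")
        return 0.0
    hop = _hop_distance_matrix(g) if hop is None else hop
    iu = np.triu_indices(g.n_vertices, k=1)
    d = hop[iu]
    d = d[np.isfinite(d) & (d >= 1)]
    diameter = int(d.max())
    if diameter < 2:
        warnings.warn("diameter <= 1: hop plot fit degenerate, exponent set to 0")
        return 0.0
    hs = np.arange(1, diameter + 1)
    n_h = np.array([(d <= h).sum() for h in hs], dtype=float)
    slope = np.polyfit(np.log(hs), np.log(n_h), 1)[0]
    return float(slope)


def component_metrics(g: CellGraph) -> dict:
    """Giant-component ratio and component counts.

    Components of a single node count toward the giant-component ratio's
    denominator but are excluded from the component count and mean size
    (an isolated nucleus is not a cluster).
    """
    _require_nonempty(g)
    n = g.n_vertices
    if g.n_edges == 0:
        sizes = np.ones(n, dtype=int)
    else:
        _, labels = connected_components(_sparse_adjacency(g), directed=False)
        sizes = np.bincount(labels)
    nontrivial = sizes[sizes >= 2]
    return {
        "gcc_ratio": float(sizes.max()) / n,
        "n_connected_components": float(nontrivial.size),
        "avg_component_size": float(nontrivial.mean()) if nontrivial.size else 0.0,
    }


def point_percentages(g: CellGraph) -> dict:
    """Percentage of isolated (degree 0) and end (degree 1) points."""
    _require_nonempty(g)
    deg = g.degrees()
    return {
        "pct_isolated_points": 100.0 * float(np.sum(deg == 0)) / g.n_vertices,
        "pct_end_points": 100.0 * float(np.sum(deg == 1)) / g.n_vertices,
    }


def edge_length_stats(g: CellGraph) -> dict:
    """Moments of the edge-length distribution.

    mean; sample standard deviation (n-1); skewness m3 / m2^(3/2) and
    non-excess kurtosis m4 / m2^2 with population central moments.  An
    edgeless graph or a zero-variance length distribution yields 0s with a
    warning.
    """
    _require_nonempty(g)
    lengths = np.asarray(g.lengths, dtype=float)
    if lengths.size == 0:
        warnings.warn("no edges: edge length statistics set to 0")
        return {
            "mean_edge_length": 0.0,
            "std_edge_length": 0.0,
            "skewness_edge_length": 0.0,
            "kurtosis_edge_length": 0.0,
        }
    mean = float(lengths.mean())
    std = float(lengths.std(ddof=1)) if lengths.size >= 2 else 0.0
    centred = lengths - mean
    m2 = float(np.mean(centred**2))
    if m2 == 0.0:
        warnings.warn("all edge lengths equal: skewness/kurtosis set to 0")
        skew, kurt = 0.0, 0.0
    else:
        skew = float(np.mean(centred**3)) / m2**1.5
        kurt = float(np.mean(centred**4)) / m2**2
    return {
        "mean_edge_length": mean,
        "std_edge_length": std,
        "skewness_edge_length": skew,
        "kurtosis_edge_length": kurt,
    }


def compute_metric_vector(g: CellGraph) -> MetricVector:
    """Assemble all 20 metrics in the fixed index order."""
    _require_nonempty(g)
    hop = _hop_distance_matrix(g) if g.n_edges else None
    record: dict = {"average_degree": average_degree(g)}
    record.update(clustering_coefficients(g))
    record.update(eccentricity_metrics(g, hop=hop))
    record["average_path_length"] = average_path_length(g, hop=hop)
    record["hop_plot_exponent"] = hop_plot_exponent(g, hop=hop)
    record.update(component_metrics(g))
    record.update(point_percentages(g))
    record.update(edge_length_stats(g))
    return MetricVector(
        values=np.array([record[name] for name in METRIC_NAMES]),
        sample_id=g.sample_id,
        cell_line=g.cell_line,
        time_h=g.time_h,
        replicate=g.replicate,
    )


def metrics_table(graphs) -> pd.DataFrame:
    """Batch metric extraction: one row per graph, labels + 20 columns."""
    rows = [compute_metric_vector(g).to_row() for g in graphs]
    return pd.DataFrame(rows, columns=LABEL_COLUMNS + METRIC_NAMES)
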