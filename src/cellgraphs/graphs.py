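"""Distance-thresholded cell-graph construction.

A cell-graph is the simple undirected geometric graph on nuclei centroids
in which two nuclei are linked exactly when their 3D Euclidean distance is
below a threshold D.  The convention is a *strict* inequality (a pair at
exactly D is not linked); D defaults to 75 um, the threshold at which
hydrogel graphs are neither too sparse (60 um) nor too dense (90 um).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import PointCloud

__all__ = ["CellGraph", "build_cell_graph", "edge_length_list", "DEFAULT_THRESHOLD_UM"]

DEFAULT_THRESHOLD_UM = 75.0


@dataclass
class CellGraph:
    """Simple geometric graph: nuclei vertices, sub-threshold edges."""

    coords: np.ndarray  # (n, 3) um
    edges: np.ndarray  # (m, 2) int vertex indices, u < v
    lengths: np.ndarray  # (m,) um Euclidean edge lengths
    threshold_um: float
    sample_id: str = ""
    cell_line: str = ""
    time_h: float = float("nan")
    replicate: int = 0

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_vertices, dtype=int)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def adjacency(self) -> np.ndarray:
        """Dense boolean adjacency matrix (small graphs only)."""
        a = np.zeros((self.n_vertices, self.n_vertices), dtype=bool)
        if self.n_edges:
            a[self.edges[:, 0], self.edges[:, 1]] = True
            a[self.edges[:, 1], self.edges[:, 0]] = True
        return a

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(
            threshold_um=self.threshold_um,
            sample_id=self.sample_id,
            cell_line=self.cell_line,
            time_h=self.time_h,
            replicate=self.replicate,
        )
        for i, (x, y, z) in enumerate(self.coords):
            g.add_node(i, x_um=float(x), y_um=float(y), z_um=float(z))
        for (u, v), length in zip(self.edges, self.lengths):
            g.add_edge(int(u), int(v), length_um=float(length))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "CellGraph":
        nodes = sorted(g.nodes)
        index = {node: i for i, node in enumerate(nodes)}
        coords = np.array(
            [[g.nodes[n]["x_um"], g.nodes[n]["y_um"], g.nodes[n]["z_um"]] for n in nodes],
            dtype=float,
        ).reshape(-1, 3)
        edges, lengths = [], []
        for u, v, data in g.edges(data=True):
            i, j = sorted((index[u], index[v]))
            edges.append((i, j))
            lengths.append(data["length_um"])
        order = np.lexsort(
            (np.array([e[1] for e in edges]), np.array([e[0] for e in edges]))
        ) if edges else []
        edges_arr = np.array(edges, dtype=int).reshape(-1, 2)[order]
        lengths_arr = np.array(lengths, dtype=float)[order] if len(lengths) else np.empty(0)
        return cls(
            coords=coords,
            edges=edges_arr,
            lengths=lengths_arr,
            threshold_um=float(g.graph.get("threshold_um", np.nan)),
            sample_id=str(g.graph.get("sample_id", "")),
            cell_line=str(g.graph.get("cell_line", "")),
            time_h=float(g.graph.get("time_h", np.nan)),
            replicate=int(g.graph.get("replicate", 0)),
        )

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def read_graphml(cls, path) -> "CellGraph":
        return cls.from_networkx(nx.read_graphml(path, node_type=int))

    def edge_list_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"u": self.edges[:, 0], "v": self.edges[:, 1], "length_um": self.lengths}
        )


def build_cell_graph(
    cloud: PointCloud,
    threshold_um: float = DEFAULT_THRESHOLD_UM,
    inclusive: bool = False,
) -> CellGraph:
    """Link every nuclei pair closer than ``threshold_um`` (strict '<').

    Set ``inclusive=True`` for a '<=' comparison; ties at exactly D are
    measure-zero for real data but the convention is explicit.  Duplicate
    coordinates are legal (distance 0 < D gives an edge); NaN coordinates
    are rejected by :class:`PointCloud` itself.
    """
    if not (threshold_um > 0):
        raise ValueError("threshold_um must be strictly positive")
    coords = np.asarray(cloud.coords, dtype=float)
    if coords.size and not np.isfinite(coords).all():
        raise ValueError("point cloud contains non-finite coordinates")
    n = coords.shape[0]
    if n >= 2:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(threshold_um, output_type="ndarray")  # d <= D
        if pairs.size:
            lengths = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
            if not inclusive:
                keep = lengths < threshold_um
                pairs, lengths = pairs[keep], lengths[keep]
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs, lengths = pairs[order], lengths[order]
        else:
            lengths = np.empty(0)
    else:
        pairs = np.empty((0, 2), dtype=int)
        lengths = np.empty(0)
    return CellGraph(
        coords=coords,
        edges=np.asarray(pairs, dtype=int).reshape(-1, 2),
        lengths=lengths,
        threshold_um=float(threshold_um),
        sample_id=cloud.sample_id,
        cell_line=cloud.cell_line,
        time_h=cloud.time_h,
        replicate=cloud.replicate,
    )


def edge_length_list(g: CellGraph) -> np.ndarray:
    """Edge lengths in um, one per edge (an order-free multiset)."""
    return np.asarray(g.lengths, dtype=float).copy()
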