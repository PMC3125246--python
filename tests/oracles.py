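"""Independent brute-force oracles for cross-checking the package.

Everything here is deliberately naive pure Python (dict/list loops, no
scipy.sparse/csgraph, no scikit-image), so that agreement with the
package's vectorised implementations is a genuine dual-route check.
"""

from __future__ import annotations

import itertools
import math


def floyd_warshall(n: int, edges) -> list[list[float]]:
    """All-pairs hop distances by the textbook O(n^3) recurrence."""
    inf = math.inf
    d = [[0.0 if i == j else inf for j in range(n)] for i in range(n)]
    for u, v in edges:
        d[u][v] = 1.0
        d[v][u] = 1.0
    for k in range(n):
        dk = d[k]
        for i in range(n):
            dik = d[i][k]
            if dik == inf:
                continue
            di = d[i]
            for j in range(n):
                alt = dik + dk[j]
                if alt < di[j]:
                    di[j] = alt
    return d


def adjacency_sets(n: int, edges) -> list[set]:
    nbrs = [set() for _ in range(n)]
    for u, v in edges:
        nbrs[u].add(v)
        nbrs[v].add(u)
    return nbrs


def components(n: int, edges) -> list[set]:
    """Connected components by explicit BFS."""
    nbrs = adjacency_sets(n, edges)
    seen = [False] * n
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        comp = {start}
        seen[start] = True
        frontier = [start]
        while frontier:
            nxt = []
            for u in frontier:
                for v in nbrs[u]:
                    if not seen[v]:
                        seen[v] = True
                        comp.add(v)
                        nxt.append(v)
            frontier = nxt
        comps.append(comp)
    return comps


def metric_vector(n: int, edges, lengths) -> dict:
    """All 20 metrics by direct enumeration; keys = package metric names."""
    nbrs = adjacency_sets(n, edges)
    deg = [len(s) for s in nbrs]
    m = len(edges)
    out = {"average_degree": 2.0 * m / n}

    # clustering coefficients
    c_v, d_v = [], []
    for v in range(n):
        k = deg[v]
        e_v = sum(
            1 for a, b in itertools.combinations(sorted(nbrs[v]), 2) if b in nbrs[a]
        )
        c_v.append(e_v / (k * (k - 1) / 2.0) if k >= 2 else 0.0)
        d_v.append((k + e_v) / ((k + 1) * k / 2.0) if k >= 1 else 0.0)
    nonisolated = [v for v in range(n) if deg[v] >= 1]
    out["clustering_coefficient_c"] = sum(c_v) / n
    out["clustering_coefficient_d"] = sum(d_v) / n
    out["clustering_coefficient_e"] = (
        sum(c_v[v] for v in nonisolated) / len(nonisolated) if nonisolated else 0.0
    )

    # hop-distance metrics over non-isolated nodes
    dist = floyd_warshall(n, edges)
    if nonisolated:
        ecc = [
            max(dist[v][u] for u in range(n) if math.isfinite(dist[v][u]))
            for v in nonisolated
        ]
        radius = min(ecc)
        out["average_eccentricity"] = sum(ecc) / len(ecc)
        out["diameter"] = max(ecc)
        out["radius"] = radius
        n_central = sum(1 for e in ecc if e == radius)
        out["n_central_points"] = float(n_central)
        out["pct_central_points"] = 100.0 * n_central / n
    else:
        for key in ("average_eccentricity", "diameter", "radius",
                    "n_central_points", "pct_central_points"):
            out[key] = 0.0

    finite_pairs = [
        dist[i][j]
        for i in range(n)
        for j in range(i + 1, n)
        if math.isfinite(dist[i][j])
    ]
    out["average_path_length"] = (
        sum(finite_pairs) / len(finite_pairs) if finite_pairs else 0.0
    )

    # hop plot
    diameter = int(max(finite_pairs)) if finite_pairs else 0
    if diameter >= 2:
        xs, ys = [], []
        for h in range(1, diameter + 1):
            count = sum(1 for d in finite_pairs if d <= h)
            xs.append(math.log(h))
            ys.append(math.log(count))
        xbar = sum(xs) / len(xs)
        ybar = sum(ys) / len(ys)
        out["hop_plot_exponent"] = sum(
            (x - xbar) * (y - ybar) for x, y in zip(xs, ys)
        ) / sum((x - xbar) ** 2 for x in xs)
    else:
        out["hop_plot_exponent"] = 0.0

    comps = components(n, edges)
    sizes = [len(c) for c in comps]
    nontrivial = [s for s in sizes if s >= 2]
    out["gcc_ratio"] = max(sizes) / n
    out["n_connected_components"] = float(len(nontrivial))
    out["avg_component_size"] = (
        sum(nontrivial) / len(nontrivial) if nontrivial else 0.0
    )

    out["pct_isolated_points"] = 100.0 * sum(1 for k in deg if k == 0) / n
    out["pct_end_points"] = 100.0 * sum(1 for k in deg if k == 1) / n

    # edge length moments
    if lengths:
        mean = sum(lengths) / len(lengths)
        out["mean_edge_length"] = mean
        if len(lengths) >= 2:
            out["std_edge_length"] = math.sqrt(
                sum((x - mean) ** 2 for x in lengths) / (len(lengths) - 1)
            )
        else:
            out["std_edge_length"] = 0.0
        m2 = sum((x - mean) ** 2 for x in lengths) / len(lengths)
        if m2 > 0:
            m3 = sum((x - mean) ** 3 for x in lengths) / len(lengths)
            m4 = sum((x - mean) ** 4 for x in lengths) / len(lengths)
            out["skewness_edge_length"] = m3 / m2**1.5
            out["kurtosis_edge_length"] = m4 / m2**2
        else:
            out["skewness_edge_length"] = 0.0
            out["kurtosis_edge_length"] = 0.0
    else:
        for key in ("mean_edge_length", "std_edge_length",
                    "skewness_edge_length", "kurtosis_edge_length"):
            out[key] = 0.0
    return out


def geometric_edges(coords, threshold, inclusive=False):
    """All-pairs O(n^2) geometric edge enumeration."""
    edges, lengths = [], []
    n = len(coords)
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(coords[i], coords[j])
            if d < threshold or (inclusive and d == threshold):
                edges.append((i, j))
                lengths.append(d)
    return edges, lengths


def bfs_label_3d(mask, connectivity=26):
    """Connected-component labels of a 3D boolean mask via BFS flood fill.

    Returns a dict mapping voxel index tuple -> component id (1-based,
    in scan order of the first voxel found).
    """
    if connectivity == 6:
        offsets = [
            (dz, dy, dx)
            for dz, dy, dx in itertools.product((-1, 0, 1), repeat=3)
            if abs(dz) + abs(dy) + abs(dx) == 1
        ]
    elif connectivity == 18:
        offsets = [
            o for o in itertools.product((-1, 0, 1), repeat=3)
            if 1 <= sum(abs(c) for c in o) <= 2
        ]
    else:
        offsets = [
            o for o in itertools.product((-1, 0, 1), repeat=3) if any(o)
        ]
    shape = (len(mask), len(mask[0]), len(mask[0][0]))
    fg = {
        (z, y, x)
        for z in range(shape[0])
        for y in range(shape[1])
        for x in range(shape[2])
        if mask[z][y][x]
    }
    labels = {}
    next_label = 0
    for voxel in sorted(fg):
        if voxel in labels:
            continue
        next_label += 1
        labels[voxel] = next_label
        frontier = [voxel]
        while frontier:
            nxt = []
            for z, y, x in frontier:
                for dz, dy, dx in offsets:
                    nb = (z + dz, y + dy, x + dx)
                    if nb in fg and nb not in labels:
                        labels[nb] = next_label
                        nxt.append(nb)
            frontier = nxt
    return labels


def otsu_brute_force(values, n_bins=256):
    """Between-class-variance-maximising threshold over histogram bins."""
    lo, hi = min(values), max(values)
    width = (hi - lo) / n_bins
    counts = [0] * n_bins
    for v in values:
        b = min(int((v - lo) / width), n_bins - 1)
        counts[b] += 1
    centers = [lo + (b + 0.5) * width for b in range(n_bins)]
    total = len(values)
    best_sigma, best_t = -1.0, None
    for t in range(n_bins - 1):
        w0 = sum(counts[: t + 1])
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(c * x for c, x in zip(counts[: t + 1], centers[: t + 1])) / w0
        mu1 = sum(c * x for c, x in zip(counts[t + 1 :], centers[t + 1 :])) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_sigma, best_t = sigma, centers[t]
    return best_t


def ks_statistic(x, y):
    """sup |F_x - F_y| over the pooled support, by direct counting."""
    best = 0.0
    for t in sorted(set(x) | set(y)):
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best
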