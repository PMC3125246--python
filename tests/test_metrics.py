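"""The 20 structural metrics: hand-enumerated small graphs, brute-force
oracle equivalence, and structural invariants."""

import numpy as np
import pytest

from cellgraphs import PointCloud, build_cell_graph, compute_metric_vector
from cellgraphs.graphs import CellGraph
from cellgraphs.metrics import (
    METRIC_NAMES,
    average_degree,
    average_path_length,
    clustering_coefficients,
    component_metrics,
    eccentricity_metrics,
    edge_length_stats,
    hop_plot_exponent,
    point_percentages,
)

import oracles


def graph_from_edges(n, edges, lengths=None):
    """Build a CellGraph with prescribed topology (coords spread far apart,
    edges injected directly so topology is exactly as given)."""
    coords = np.column_stack([np.arange(n) * 1000.0, np.zeros(n), np.zeros(n)])
    edges = np.array(sorted(tuple(sorted(e)) for e in edges), dtype=int).reshape(-1, 2)
    if lengths is None:
        lengths = np.ones(len(edges))
    return CellGraph(coords=coords, edges=edges, lengths=np.asarray(lengths, float),
                     threshold_um=75.0)


TRIANGLE = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
PATH3 = graph_from_edges(3, [(0, 1), (1, 2)])
STAR3_ISO = graph_from_edges(5, [(0, 1), (0, 2), (0, 3)])  # node 4 isolated


def test_triangle_basics():
    assert average_degree(TRIANGLE) == 2.0
    cc = clustering_coefficients(TRIANGLE)
    assert cc == {
        "clustering_coefficient_c": 1.0,
        "clustering_coefficient_d": 1.0,
        "clustering_coefficient_e": 1.0,
    }
    ecc = eccentricity_metrics(TRIANGLE)
    assert ecc["diameter"] == 1 and ecc["radius"] == 1 and ecc["n_central_points"] == 3
    assert average_path_length(TRIANGLE) == 1.0
    with pytest.warns(UserWarning):
        assert hop_plot_exponent(TRIANGLE) == 0.0  # diameter 1: degenerate fit


def test_path3_hand_enumeration():
    cc = clustering_coefficients(PATH3)
    assert cc["clustering_coefficient_c"] == 0.0
    assert cc["clustering_coefficient_d"] == pytest.approx(8 / 9)
    assert cc["clustering_coefficient_e"] == 0.0
    ecc = eccentricity_metrics(PATH3)
    assert ecc["average_eccentricity"] == pytest.approx(5 / 3)
    assert ecc["diameter"] == 2 and ecc["radius"] == 1
    assert ecc["n_central_points"] == 1
    assert ecc["pct_central_points"] == pytest.approx(100 / 3)
    assert average_path_length(PATH3) == pytest.approx(4 / 3)
    # hop plot: points (1, 2), (2, 3) -> slope log(3/2)/log 2
    assert hop_plot_exponent(PATH3) == pytest.approx(np.log(1.5) / np.log(2))
    pp = point_percentages(PATH3)
    assert pp["pct_isolated_points"] == 0.0
    assert pp["pct_end_points"] == pytest.approx(200 / 3)


def test_star_with_isolated_node():
    cc = clustering_coefficients(STAR3_ISO)
    assert cc["clustering_coefficient_c"] == 0.0
    assert cc["clustering_coefficient_e"] == 0.0  # leaves and hub all have C_v = 0
    comp = component_metrics(STAR3_ISO)
    assert comp["gcc_ratio"] == pytest.approx(0.8)
    assert comp["n_connected_components"] == 1
    assert comp["avg_component_size"] == 4
    pp = point_percentages(STAR3_ISO)
    assert pp["pct_isolated_points"] == 20.0
    assert pp["pct_end_points"] == 60.0


def test_triangle_plus_isolated_components():
    g = graph_from_edges(4, [(0, 1), (1, 2), (0, 2)])
    comp = component_metrics(g)
    assert comp["gcc_ratio"] == 0.75
    assert comp["n_connected_components"] == 1
    assert comp["avg_component_size"] == 3


def test_all_isolated_degenerate_contract():
    g = graph_from_edges(4, [])
    comp = component_metrics(g)
    assert comp["gcc_ratio"] == 0.25
    assert comp["n_connected_components"] == 0
    assert comp["avg_component_size"] == 0
    with pytest.warns(UserWarning):
        ecc = eccentricity_metrics(g)
    assert set(ecc.values()) == {0.0}
    pp = point_percentages(g)
    assert pp["pct_isolated_points"] == 100.0 and pp["pct_end_points"] == 0.0


def test_two_disjoint_edges_path_length():
    g = graph_from_edges(4, [(0, 1), (2, 3)])
    assert average_path_length(g) == 1.0  # only within-component pairs count


def test_edge_length_moment_conventions():
    g = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)], lengths=[3.0, 4.0, 5.0])
    stats = edge_length_stats(g)
    assert stats["mean_edge_length"] == 4.0
    assert stats["std_edge_length"] == pytest.approx(1.0)
    g_eq = graph_from_edges(3, [(0, 1), (1, 2)], lengths=[7.0, 7.0])
    with pytest.warns(UserWarning):
        stats_eq = edge_length_stats(g_eq)
    assert stats_eq["std_edge_length"] == 0.0
    assert stats_eq["skewness_edge_length"] == 0.0
    assert stats_eq["kurtosis_edge_length"] == 0.0


def test_symmetric_lengths_have_near_zero_skewness(rng):
    lengths = rng.uniform(10, 50, size=500)
    lengths = np.concatenate([lengths, 60 - lengths])  # exactly symmetric pool
    g = graph_from_edges(
        1000, [(2 * i, 2 * i + 1) for i in range(500)] +
        [(2 * i + 1, (2 * i + 2) % 1000) for i in range(500)],
        lengths=lengths,
    )
    assert abs(edge_length_stats(g)["skewness_edge_length"]) < 0.2


def test_metric_vector_complete_and_ordered(geometric_graph_factory):
    mv = compute_metric_vector(geometric_graph_factory())
    assert mv.values.shape == (20,)
    assert list(mv.as_dict()) == METRIC_NAMES


def test_triangle_vector_leading_indices():
    v = compute_metric_vector(TRIANGLE).values
    assert tuple(v[:4]) == (2.0, 1.0, 1.0, 1.0)


def test_empty_graph_rejected():
    g = graph_from_edges(1, [])
    g.coords = np.empty((0, 3))
    with pytest.raises(ValueError):
        compute_metric_vector(g)


def test_permutation_invariance(rng, geometric_graph_factory):
    g = geometric_graph_factory(n=25)
    perm = rng.permutation(g.n_vertices)
    inv = np.argsort(perm)
    permuted = build_cell_graph(PointCloud(g.coords[perm]), g.threshold_um)
    v1 = compute_metric_vector(g).values
    v2 = compute_metric_vector(permuted).values
    assert np.allclose(v1, v2, atol=1e-9)


def test_rigid_motion_and_scaling_behaviour(rng):
    coords = rng.uniform(0, 100, size=(30, 3))
    g = build_cell_graph(PointCloud(coords), 45)
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    g_rot = build_cell_graph(PointCloud(coords @ q.T + 5.0), 45)
    v, v_rot = compute_metric_vector(g).values, compute_metric_vector(g_rot).values
    assert np.allclose(v, v_rot, atol=1e-8)  # all metrics rigid-motion invariant
    s = 3.0
    g_scaled = build_cell_graph(PointCloud(coords * s), 45 * s)
    v_s = compute_metric_vector(g_scaled).values
    assert np.allclose(v_s[:16], v[:16], atol=1e-9)  # topology unchanged
    assert np.allclose(v_s[16:18], s * v[16:18])  # mean/std scale linearly
    assert np.allclose(v_s[18:], v[18:], atol=1e-9)  # shape moments invariant


def _oracle_vector(g):
    return oracles.metric_vector(
        g.n_vertices, [tuple(e) for e in g.edges.tolist()], list(g.lengths)
    )


@pytest.mark.parametrize("trial", range(25))
def test_random_graphs_match_brute_force_oracle(trial, geometric_graph_factory):
    g = geometric_graph_factory()
    got = compute_metric_vector(g).as_dict()
    expected = _oracle_vector(g)
    for name in METRIC_NAMES:
        assert got[name] == pytest.approx(expected[name], abs=1e-9), name


def test_eccentricity_inequalities_on_connected_graphs(geometric_graph_factory):
    checked = 0
    for _ in range(40):
        g = geometric_graph_factory(n=15, box=60.0, threshold=45.0)
        comp = component_metrics(g)
        if comp["gcc_ratio"] < 1.0:  # inequality chain assumes connectivity
            continue
        checked += 1
        ecc = eccentricity_metrics(g)
        r, a, d = ecc["radius"], ecc["average_eccentricity"], ecc["diameter"]
        assert r <= a <= d <= 2 * r
    assert checked >= 5
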