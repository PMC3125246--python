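"""Build a 75-um cell-graph from a point cloud and read its 20 metrics.

Compares one uniform and one clustered archetype at the same time point:
clustering coefficients and component structure respond to spatial
organisation, edge-length moments to local spacing.
"""

from cellgraphs import (
    VolumeSpec,
    build_cell_graph,
    compute_metric_vector,
    default_archetypes,
    sample_point_cloud,
)

vol = VolumeSpec()
archetypes = {a.name: a for a in default_archetypes()}

for name in ("RWPE-1", "MG63"):  # uniform vs compact-clustered
    cloud = sample_point_cloud(archetypes[name], vol, seed=42)
    graph = build_cell_graph(cloud, threshold_um=75.0)
    mv = compute_metric_vector(graph).as_dict()
    print(f"\n{name}: {graph.n_vertices} nuclei, {graph.n_edges} edges at D = 75 um")
    for key in ("average_degree", "clustering_coefficient_d", "gcc_ratio",
                "n_connected_components", "pct_isolated_points",
                "mean_edge_length", "std_edge_length"):
        print(f"  {key:28s} {mv[key]:8.3f}")
# The clustered archetype shows higher clustering coefficients and more,
# smaller components; the uniform one a larger giant-component ratio.
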