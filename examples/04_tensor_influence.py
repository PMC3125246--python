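"""Rank metric influence by three-way tensor decomposition.

Simulates the full design, assembles the 20 x 6 x 11 feature-time-line
tensor (replicates averaged), normalizes it (double centering + feature
autoscaling), selects parsimonious Tucker3 dims by the DIFFIT knee, and
ranks features by Hotelling's T^2 in factor-score space.
"""

from cellgraphs import (
    assemble_tensor,
    build_cell_graph,
    default_archetypes,
    fit_tucker3,
    generate_time_course,
    influence_scores,
    metrics_table,
    normalize_tensor,
    select_dims_diffit,
)

clouds = generate_time_course(default_archetypes(), replicates=5, seed=0)
table = metrics_table(build_cell_graph(c) for c in clouds)
tensor = assemble_tensor(table)
normalized, record = normalize_tensor(tensor)
dims = select_dims_diffit(normalized)
model = fit_tucker3(normalized, dims)
scores = influence_scores(model, top_k=5)

print(f"tensor {tensor.shape} (feature x time x line); Tucker3 dims {dims}, "
      f"{model.explained_variation_pct:.1f}% of variation explained")
print("\nmetrics by influence (top 10):")
frame = scores.to_frame().sort_values("combined_rank").head(10)
for _, row in frame.iterrows():
    mark = "*" if row.selected else " "
    print(f" {mark} {row.feature:28s} T2 = {row.hotelling_t2:7.2f}   SSR = {row.ssr:6.2f}")
# Starred metrics form the top-5 set used downstream for pairwise
# discrimination; high T^2 = the metric's time-by-line profile carries
# strong systematic structure relative to the panel.
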