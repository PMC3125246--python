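# Methods

This note records the models, conventions, and design choices behind
`cellgraphs`, in the order the pipeline applies them, plus what the
synthetic data does and does not emulate.

## Synthetic hydrogel cultures

The generator emulates the acquisition design the package targets: a
900 × 900 × 100 µm hydrogel volume imaged at six fixation times (hours 10,
16, 24, 72, 120, 168), five replicate samples per time point, across a
panel of 11 cell-line archetypes. Two spatial regimes are provided:

- **uniform** — homogeneous Poisson process: N ~ Poisson(λ·V) nuclei placed
  independently and uniformly in the box;
- **clustered** — Thomas process: Poisson cluster parents (rate κ per µm³),
  Poisson(µ) offspring per parent, isotropic Gaussian displacements of
  scale σ µm. Offspring falling outside the box are discarded — the box is
  an imaging window, not a torus, so cluster fragments at the boundary look
  like real edge effects.

The Thomas process was chosen because it is the simplest standard cluster
process with separately interpretable knobs for clustering strength (κ, µ)
and cluster tightness (σ). Archetype parameters drift over the time course
via per-time-point multipliers, modelling proliferation (rates up ~2–3×
over the week) and cluster compaction (σ down ~25–35 %).

The default panel spans expected counts of ~70–260 nuclei per volume at the
first time point — a realistic seeding-density range that yields 75-µm
graphs between sparse (average degree ≈ 1) and locally dense (≈ 8). Nuclei
counts per stack are configuration, not constants; nothing downstream
assumes them. Two archetypes (AU565 and MDA-MB231) share identical
parameters by design: they are the panel's negative control, the pair a
correct discrimination analysis must *fail* to separate.

What the generator does **not** emulate: cell migration and collagen
remodelling dynamics (the time course is a sequence of independent draws,
not a trajectory), nucleus shape and intensity heterogeneity, optical
artefacts (attenuation with depth, PSF anisotropy beyond voxel size), and
touching/overlapping nuclei. Passing tests therefore demonstrate the
correctness and sensitivity of the analysis chain under controlled spatial
statistics — not segmentation robustness on difficult real microscopy.

Image rendering places an isotropic Gaussian intensity blob (default
σ = 3 µm — a nucleus-scale footprint; the actual nuclear diameter is not a
modelled quantity) at each centroid on the anisotropic voxel grid (default
2.0 × 1.76 × 1.76 µm z/y/x), adds Gaussian background noise, clips at zero.

## Segmentation

A single global Otsu threshold (256 histogram bins by default) binarizes
the whole stack; foreground is *strictly greater than* the threshold.
Connected components are labelled in 3D with 26-connectivity by default
(the most permissive; diagonal voxel chains of one nucleus stay one
component), configurable to 6 or 18. Components smaller than `min_voxels`
(default 4, settable to 1) are discarded as speckle. Centroids are
unweighted means of member-voxel centres under the convention that voxel
(k, j, i) has centre ((i+0.5)·sx, (j+0.5)·sy, (k+0.5)·sz) µm. Otsu and
labelling are metric-free; anisotropic spacing enters only at centroid
extraction, and stacks are not resampled. There is no watershed splitting:
nuclei closer than about one blob diameter merge, which bounds the regime
in which count recovery can be exact (tests use separations > 6σ).

A constant-intensity stack has no foreground/background structure and
raises a degenerate-histogram error rather than returning an arbitrary
threshold.

## Cell-graphs and metrics

Edges link pairs at Euclidean distance strictly below D (default 75 µm);
the comparison is configurable to ≤, but ties at exactly D are measure-zero
for real data. Distances are 3D (z included), since centroids come from
z-stacks. Construction uses a k-d tree and agrees exactly with the O(n²)
all-pairs definition.

The 20 metrics follow fixed conventions, chosen once and kept:

- **Clustering coefficients.** With e_v = edges among the neighbours of v
  and k = deg v: C_v = e_v / C(k,2) for k ≥ 2 else 0; D_v = (k + e_v) /
  C(k+1,2) for k ≥ 1 else 0. C and D average over *all* nodes (degree-<2
  nodes contribute 0 rather than being dropped or NaN, so every graph is
  scorable); E averages C_v over non-isolated nodes only.
- **Hop-count metrics.** Hydrogel graphs are usually disconnected, so
  eccentricities and path lengths are computed within connected components
  over non-isolated nodes: eccentricity is the max hop distance to any
  *reachable* node; average path length averages over same-component
  pairs. Central points are the considered nodes at eccentricity = radius;
  their percentage (like the isolated/end-point percentages) uses all
  nodes in the denominator. An all-isolated graph yields zeros with a
  warning. Note one consequence: any two-node component has eccentricity 1,
  so the graph radius of a fragmented graph is almost always 1 — a
  near-degenerate metric in that regime.
- **Hop plot.** N(h) counts unordered same-component pairs within h hops,
  h = 1..diameter; the exponent is the OLS slope in (log h, log N). A
  diameter ≤ 1 gives no fit and yields 0 with a warning.
- **Components.** The giant-component ratio uses all nodes; the component
  count and mean size exclude single-node components (an isolated nucleus
  is not a cluster).
- **End points** are nodes of degree exactly 1 (the isolated/end
  distinction is degree 0 vs degree 1).
- **Edge-length moments.** Mean; sample SD (n−1); skewness m₃/m₂^{3/2} and
  *non-excess* kurtosis m₄/m₂² with population central moments. Degenerate
  cases (no edges; all lengths equal) yield 0 with warnings.

All 20 metrics are validated against independent pure-Python brute-force
oracles (adjacency enumeration, Floyd–Warshall, BFS) on random geometric
graphs to 1e−9.

## Tensor normalization and decomposition

Replicates are averaged at assembly (the tensor has no replicate mode).
Normalization is sequential: (1) for each (feature, line) fibre subtract
its mean over time; (2) for each (feature, time) fibre subtract its mean
over lines; (3) divide each feature's J × K slice by that slice's standard
deviation (n−1 over the JK entries). The order time-then-line is a
convention (config-exposed); the record of means and SDs makes the
transform exactly invertible. After step 3 every feature slice has equal
total variance — a fact with consequences for influence (below). A
zero-variance feature slice raises, naming the feature.

**Tucker3** is fitted by higher-order orthogonal iteration: HOSVD
(truncated mode-wise SVD) initialisation plus a small number of random
orthonormal restarts (HOOI has genuine local optima — observed even on
small random tensors), relative-fit tolerance 1e−8, core G = T contracted
with the factor transposes, E = T − reconstruction, explained variation =
100·(1 − ‖E‖²/‖T‖²). `tucker_fit_grid` evaluates the whole admissible
(P, Q, R) lattice in increasing total order, warm-starting each fit from
orthonormally expanded sub-model solutions; since an expanded initialisation
reproduces its parent's fit and HOOI never decreases fit, the grid is
monotone along the lattice by construction.

**PARAFAC** uses alternating least squares with an SVD-based start plus
random multi-starts (best fit kept), tolerance 1e−8, components normalised
to unit factor columns with non-negative weights sorted descending, signs
pinned by making the dominant entry of each B and C column positive. A
two-factor congruence above 0.85 (degeneracy indicator) is logged.

### Component-count selection

Two selectors are provided:

- `select_components(T, 0.95)` — per mode, the smallest number of leading
  singular values of the unfolding whose cumulative energy reaches the
  threshold (default 95 %). On strongly structured data this is
  parsimonious; on data where many features are weakly structured it
  saturates, because autoscaled noise features carry a large fixed energy
  share that forces near-full dims.
- `select_dims_diffit(T)` — the DIFFIT heuristic: Tucker fit over the dims
  lattice, best fit per total component count s, and s* chosen at the
  maximum fit-gain salience ratio dif(s)/dif(s+1) among totals gaining more
  than 0.5 percentage points. This locates the knee where added components
  stop capturing systematic structure and is the pipeline default, because
  the influence statistics below are only informative on a parsimonious
  model.

### Feature influence

For a fitted model, feature i's score vector is row i of the feature-mode
factor matrix (weights absorbed for PARAFAC). Hotelling's T² is the
variance-normalised squared deviation of those scores from the column
means (diagonal-covariance Mahalanobis distance in score space); SSR is
the sum of squared residuals over the feature's slice.

Because autoscaling equalises slice variance, SSR is the complement of the
structure a parsimonious model captures: features with strong systematic
time-by-line profiles have high T² *and low* SSR, and a ranking that
rewards both large T² and large SSR is internally contradictory — on
planted-signal tensors it is anti-informative. The default ranking is
therefore by T² alone (SSR is reported as a complementary diagnostic of
how much of a feature remains unexplained); a rank-sum combination of
descending T² and SSR ranks remains available via
`influence_scores(..., combine="ranksum")`. The top-k set (default k = 5)
feeds the discrimination stage. On planted-influence tensors (5 structured
features among 15 pure-noise ones, signal/noise = 5) the default
DIFFIT + T² procedure recovers ≥ 4 of 5 planted features in essentially
every seed.

## Two-way influence

For condition × feature matrices the analysis autoscales columns,
decomposes by SVD with deterministic sign convention, selects K by the
same 95 % rule (or an explicit K), and scores feature m by
Σ_{k≤K} |V_mk·s_k| (configurable to unweighted |V_mk|; whether "factor
scores" should carry the singular values is ambiguous in common usage, so
both are implemented). Two caveats are intrinsic and documented rather
than patched: (i) with very few conditions, a pure-noise column's chance
alignment with a K-dimensional signal subspace of the (n−1)-dimensional
row space has expected R² = K/(n−1), so separation claims need either few
components or more conditions; (ii) after autoscaling, influence reflects
correlation *structure* only, so K should reflect known latent
dimensionality (e.g. a tissue-type count) — it is overridable for exactly
this reason. Zero-variance columns (e.g. the radius metric on fragmented
graphs) raise by default or can be dropped with `on_degenerate="drop"`.

## Discrimination and trends

The two-sample KS test uses the classical asymptotic p-value: D = sup of
the empirical-CDF difference over the pooled sample, p = Q_K(√(n_e)·D)
with effective size n_e = n_x·n_y/(n_x+n_y); reject iff p < α (default
0.10). At the default design each line contributes 30 pooled values per
metric (5 replicates × 6 time points); pooling across time means the test
compares whole temporal trajectories. Per-time-point testing is available
(`per_time=True`). No multiple-testing correction is applied across the
five metrics or the line pairs — the OR at the nominal level is the
method's combination rule — though a Bonferroni option exists.

Calibration note: with n = 30 vs 30 the statistic is discrete (multiples
of 1/30) and the rejection region at α = 0.10 is D ≥ 10/30, whose exact
null probability is ≈ 0.072. The attainable test size is therefore ≈ 7 %,
not 10 %; this is a property of the KS test at this sample size, not of
the implementation.

Trend profiles compare early (hours 10, 16) and late (hours 120, 168)
means per (line, metric): percent change 100·(late − early)/|early|
(undefined and flagged when the early mean is exactly 0), binned into
signed steps at |Δ| = 10 / 50 / 150 % (flat below 10 %); the edges are
configuration.

## Pipeline and reproducibility

All method constants (D = 75 µm, 95 % variance threshold, α = 0.10,
top-5, six time points, five replicates) surface as `PipelineConfig`
defaults and are never hard-coded in stage code. Randomness flows from a
single seed through `numpy.random.SeedSequence` spawns, one per sample;
identical config + seed gives byte-identical artifacts (CSV floats are
written with a fixed format; logs carry no timestamps). Stage failures
abort with the stage name and offending sample id.

## Problem sizes used in validation

The test-suite and acceptance checks run at desk scale, chosen as the
package's own validation design: metric-oracle equivalence on 100 random
geometric graphs of up to 40 nodes; graph-construction oracle on 50 clouds
up to 120 points; segmentation recovery on a 300 × 250 × 60 µm stack with
30 planted nuclei; influence recovery over 20 planted 20 × 6 × 11 tensors;
KS calibration over 2000 null pairs; and 10 full end-to-end pipeline runs
of the 330-sample default design.

## Known limitations

- No splitting of touching nuclei; counts are underestimated in dense
  fields, which shifts degree-related metrics.
- The radius (and to a lesser degree other hop metrics) is nearly constant
  on highly fragmented graphs; such metrics carry little signal in sparse
  regimes and can be dropped in the two-way analysis.
- PARAFAC on tensors whose true structure is Tucker-like can be degenerate;
  the congruence diagnostic flags but does not prevent this.
- The asymptotic KS p-value is conservative at n = 30 (size ≈ 7 % at
  nominal 10 %); exact small-sample tables are deliberately not used.
- Time-course samples are independent draws per time point; no temporal
  autocorrelation within a physical sample is modelled.
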