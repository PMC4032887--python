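# Methods

This note documents the models implemented in `neurotrace`, the parameter
choices that matter, the synthetic data the tests run on, and the known
limitations. All numerical results referred to here are the ones computed
by the test suite and `scripts/acceptance.py`.

## Initial tracing by multi-seed Fast Marching

The arrival-time field T solves |∇T|·I = 1 with T = 0 on the current trace
boundary; the normalized intensity I ∈ [0, 1] acts as the front speed, so
fronts run fastest along bright neurites. On the voxel lattice we use the
standard upwind (Rouy–Tourin) discretization: per axis only the smaller of
the two neighbor values enters,

    Σ_axes ( max(T − T_axis_min, 0) / s_axis )² = 1 / I²,

with the physical voxel sizes (s_x, s_y, s_z) — z is typically coarser in
confocal/two-photon stacks. Voxels with I = 0 make the update singular and
are treated as hard barriers. The solver is the classic min-heap
single-pass scheme (accept voxels in nondecreasing T); the test suite
checks it against an independent label-correcting solver that sweeps the
same update to a fixed point (agreement ≤ 10⁻⁶ on random grids).

Growth iterates: march the front until a newly accepted voxel lies farther
than D_max (Euclidean, to the nearest boundary voxel; default 15·s_x) from
the trace; walk the steepest-descent path of T on the 26-neighborhood from
the chosen target back to T = 0; add the path to the boundary; re-solve.
Discrete descent is used rather than interpolated gradients because it
provably terminates on a valid upwind map; sub-voxel accuracy is restored
by the optimizer. D_max must exceed the neurite caliber (otherwise surface
voxels spawn spurious short branches) and should not greatly exceed the
shortest branch to be resolved.

Target selection and stopping. Candidate targets are accepted foreground
voxels (intensity at or above the stop threshold) between a minimum
distance (default 4·s_x, the caliber scale) and D_max, tried in decreasing
distance order; a target whose descent path has mean intensity below
`stop_fraction` (default 0.2) times the mean intensity of the existing
trace is rejected and its path suppressed. Growth stops when no acceptable
target remains. This realizes the stop rule "pause when the last branch is
dim" in a batch setting; a `stop_callback` hook lets an interactive caller
accept dim paths and continue.

Collisions. Fronts are labeled by the connected component of the trace
graph they grow from. When an update to a voxel draws on two labels, that
voxel is a collision; steepest-descent paths from it into both regions
join the components. A collision at a voxel dimmer than the stop threshold
is vetoed — fronts meeting mid-gap or in background do not bridge. This
preserves the two topological error classes real data produce: labeling
gaps break branches, and near-crossings of distinct bright axons merge
them (the collision voxel there is bright, so the erroneous junction is
created — deliberately: correcting it is the branch merger's job).

## Trace model

A trace is a graph of nodes (3D physical position, caliber) with arbitrary
symmetric adjacency; loops are allowed, which the SWC tree format cannot
express, so the native serialization is a JSON node/edge graph and SWC is
an export with an explicit cycle guard. Branches are maximal chains
between nodes of degree ≠ 2; isolated cycles split at their lowest node
id. Resampling subdivides each branch at uniform arc spacing while keeping
the original vertices, so the total length is preserved exactly and every
edge is at most d long.

## Trace optimization

The fitness is

    F = Σ_k Σ_m I(l_m) K_{R_k}(l_m − r_k)  −  α_r λ |D r|²  −  α_R λ |D R|²

where K_σ = −σ²∇²G_σ is the scale-normalized inverted Laplacian-of-
Gaussian, evaluated over a window truncated at 4σ and shifted to zero mean
over that window (so a uniform background contributes exactly nothing),
and λ is the node density (nodes per voxel). With the σ² normalization the
response of a tube with Gaussian cross-section σ_t is maximal at caliber
R = σ_t, so maximizing F recovers calibers as well as centerlines; on the
clean-tube benchmark recovered calibers are within a few percent of truth
and monotone in the true width.

The smoothness operator D defaults to second differences over each node's
neighbor pairs (a discrete curvature). Plain first differences are
available but not the default for a concrete reason found during
development: the intensity term is invariant to sliding nodes along a
uniform tube, and a first-difference penalty then contracts the trace
monotonically — the position term decays geometrically forever, the
relative-change stopping rule never fires, and in the limit the nodes
coalesce. Second differences vanish on uniformly spaced straight chains
and leave no such drive.

Maximization is a damped Newton method over all 4n node variables
simultaneously: finite-difference 4×4 intensity blocks per node plus the
exact sparse regularizer Hessian, shifted by a Levenberg term until the
step ascends, then a backtracking line search starting from the doubled
base step (β = 0.5 by default, so the first trial is the full Newton
step). A trust cap limits every node to one voxel of motion per accepted
step — without it, early indefinite-Hessian steps can fling chain-end
nodes off the structure. Iteration stops when the relative change of all
three fitness terms falls below 10⁻⁸ (terms negligible against the total
fitness cannot stall the test) or at `max_iter`. Per-node evaluation
windows are cached and rebuilt only when a node drifts > 1.6 voxels or its
caliber outgrows the cached support (1.5× headroom); the hysteresis keeps
the objective smooth between iterations, which both the convergence test
and the finite differences rely on.

On the clean-tube benchmark (20 tubes, σ ∈ [1.3, 2.0] voxels — the
realistic neurite caliber range — initial offset up to one voxel, mid-tube
traces) all runs converge in well under 50 iterations (median ≈ 5) with
maximal centerline error ~10⁻³ voxels.

## Branch merging

The optimized trace is dismantled: every branch becomes a free component
(junction nodes are duplicated per incident branch). Branch endpoints are
clustered by single linkage — links longer than 10·s_x are removed from
the all-to-all endpoint graph; results are insensitive to this threshold
in the 5–15·s_x range. Each scenario for a cluster of n endpoints is a set
partition: blocks of size ≥ 2 become junctions (size-2 blocks connect
directly; larger blocks get a junction node at their centroid), singletons
stay free ends. Scenario counts are the Bell numbers (2, 5, 15, 52, … for
n = 2, 3, 4, 5), enumerated in canonical restricted-growth-string order.
Enumeration is refused above n = 8 (B(8) = 4140); oversized clusters —
which arise when single linkage chains endpoints of unrelated structures —
are split by re-clustering at shrinking thresholds.

Each scenario is summarized by 9 features aggregated over merged endpoint
pairs: (1) endpoint distance, (2) overrun along the outward tangent,
(3) perpendicular offset, (4) tangent alignment −u_a·u_b, (5) |Δ branch
mean intensity|, (6) intensity standard deviation along the bridging path
(endpoint → block centroid → endpoint), (7) |Δ branch caliber|,
(8) bridging-path tortuosity, (9) number of free endpoints. Outward
tangents come from a least-squares line fit to the endpoint's last
min(5, length) nodes. These concrete formulas are this package's own
definitions of qualitatively standard cues; the extractor is a plain
function so alternatives can be swapped without touching the learners.
Scenarios are compared only within their cluster via differences
Δx = x_erroneous − x_correct, which cancels any per-cluster additive
offset (local intensity, density).

## Learning

The sign-constrained perceptron repeats: sample a violated example μ with
probability ∝ its cluster weight Q_μ; if w·Δx^μ/N < κ/N update
w ← w + Δx^μ/N; zero every weight violating its sign constraint
w_k g_k ≥ 0. Defaults: κ = 1, g = (1,1,1,0,0,0,0,0,1)ᵀ — distance,
overrun, offset and free-end-count weights constrained positive (large
values of the first three argue against merging; the last promotes
merging), the rest free. Initialization is w = g, a trivially feasible
start (the initialization is not prescribed by the model; any feasible
start works). Convergence is a full pass with no violated margins;
a non-separable set hits the update cap and is flagged.

The SVM maximizes the box-constrained dual
L(α) = (1/m)Σα_i − (1/2Nm²)Σ_ij (Δx_i·Δx_j) α_i α_j, 0 ≤ α_i ≤ C·Q_i,
with w = (1/m)Σα_iΔx_i. Since there is no equality constraint,
single-coordinate updates are exact; the solver picks the coordinate with
the largest KKT violation (greedy coordinate ascent with an incrementally
maintained score vector) and stops at KKT residual < 10⁻⁶. Default
C = 2²⁰ is effectively hard-margin. All cluster weights Q default to 1.

Confidence of a cluster is the softmax weight of its best (argmin-score)
scenario, exp(−w·x_best/T)/Σ_i exp(−w·x_i/T), T = 1 by default. For
two-scenario clusters the confidence is a monotone function of the score
gap for every T, so the query ranking is provably T-invariant there; for
clusters with many scenarios the spread changes with T and extreme
temperature ratios can in principle reorder clusters with very different
gap structures — the property test covers the pairwise case. Active
learning queries the lowest-confidence unlabeled clusters in batches,
retrains on all labels after each batch, and never re-queries a declined
cluster (mislabeled clusters are worse than no labels). Generalization
error is counted at cluster level: the whole predicted partition must
match.

## Synthetic data

`render_stack` renders tubes with Gaussian cross-sections (intensity
background + Σ amp·exp(−d²/2σ²) + Gaussian noise, clipped to [0, 1]).
Gaussian profiles are chosen deliberately: they make the LoG-optimal
caliber well-defined, so caliber recovery is testable. Labeling gaps zero
a tube's contribution over an arc interval; near-crossings place two tubes
within a voxel of each other — together these reproduce the broken-branch
and stolen-branch error classes of real dense-neuropil data. The
ground-truth trace is the resampled centerline with caliber σ. What the
phantoms do not emulate: a realistic PSF (anisotropic blur), shot noise,
varicosities/boutons, autofluorescent debris, and intensity that varies
along an axon; passing tests therefore demonstrate algorithmic
correctness under the stated model, not performance on any particular
microscope's data.

`planted_clusters` draws per-scenario feature vectors from plausible
ranges (nonnegative exponentials for distances and intensity/caliber
differences, uniform alignment, tortuosity ≥ 1, the free-end count exact)
and labels each cluster with the scenario minimizing w*·x for a fixed
planted weight vector that respects the default sign constraints; clusters
are redrawn until the best-vs-second margin is at least 0.1·|w*|, leaving
a broad mix of easy and borderline clusters — the heterogeneity active
learning exploits. On 200-cluster pools both learners recover w* to cosine
similarity > 0.99, agree on ≥ 95% of held-out clusters, and active
querying reaches < 5% cluster error within 40 labels with random querying
never better on average.

For the ground-truth labeling of rendered stacks, each endpoint is
projected onto the nearest true centerline; endpoints merge when they lie
on the same tube, face each other along its arc, and are within a 25-voxel
arc gap (ties resolved to the smallest gap). Endpoints farther than 4
voxels from every tube stay free.

## Degenerate inputs and numerical choices

- Zero-dynamic-range stacks are a normalization error; zero-intensity
  voxels never enter the marching heap.
- Gradient descent raises on a positive local minimum of T — impossible on
  a valid upwind map, so it signals a solver bug rather than silently
  truncating a path.
- The upwind quadratic solver drops axes whose neighbor value exceeds the
  candidate T (standard incremental solution) and falls back to the
  one-axis update if the discriminant is negative.
- Calibers are clamped to a minimum of 0.3 voxels; node positions are
  clamped to the stack bounds with a warning.
- `resample` keeps original polyline vertices so length is conserved
  exactly; "uniform" spacing is therefore uniform between kept vertices.
- MES point scores with an empty denominator (no gold points and no false
  positives) are defined as 1 (no errors of that kind).

## Known limitations

- On perfectly clean straight tubes the fitness is flat under sliding all
  nodes along the tube; Newton steps in that null direction are harmless
  for centerline accuracy but can redistribute nodes tangentially. Any
  realistic intensity variation pins the nodes.
- Near stack boundaries the zero-mean LoG window is clipped asymmetrically
  and caliber estimates bias low; tubes should be rendered (or imaged)
  with ≥ 4σ margins for caliber work.
- The dismantle/re-merge step trusts the branch decomposition; a missed
  branch point in the initial trace (two axons fused along an extended
  stretch rather than at a point) cannot be recovered by endpoint
  clustering.
- Front-collision vetoing uses the collision voxel's intensity; a gap
  bridged by a bright crossing artifact would still be connected, and a
  genuinely dim junction would be left split — both end up as merge
  clusters for the classifier, which is the intended correction path.
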