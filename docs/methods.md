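# Methods

## Density model

The data are N points in D features. Each feature is affinely mapped to
[0, 1] before anything else; constant columns are dropped (their [0, 1]
map is undefined and they carry no information). Because the pilot
covariance is fitted by a scale-equivariant rule, this normalization does
not change cluster assignments — it only fixes a convenient numerical
scale, and all tolerances below are quoted in these normalized
coordinates. Locations reported to the user are mapped back to the
original units.

The density estimate is a Gaussian mixture with one component per data
point. A single pilot covariance C is chosen to maximize the
leave-one-out log likelihood: each point is scored under the KDE built
from the other N−1 points, which removes the degenerate zero-bandwidth
maximizer of the plain likelihood. Setting the gradient with respect to C
to zero yields a fixed-point map — C is replaced by the average over
points i of the kernel-weighted covariance of the differences Yᵢ−Yⱼ — and
the iteration is run from the D×D identity, a deliberate overestimate on
[0, 1] data so the fixed point is approached from above. Convergence is
declared when the relative Frobenius change drops below 1e−6 (at most 500
sweeps); a 1e−10 ridge keeps the update alive on data that is degenerate
in some direction. On small 1-D sets the fixed point agrees with an
exhaustive grid search over scalar C to better than 1e−3 (tested).

Per-point covariances are then Cᵏ = λₖ C with the Abramson factors
λₖ = (f̂(Yₖ)/g)^(−1/2), where f̂ is the uniform-C pilot KDE and g the
geometric mean of its values at the data. The geometric mean of the λₖ is
exactly one, so local adaptation does not change the overall smoothing
level. The rescaling can be disabled (`abramson=False`) when structure is
suspected in the distribution tails, which local broadening would smooth
away.

The final KDE exposes analytic density, gradient and Hessian; all three
are verified against central finite differences to 1e−5 relative error,
and the density integrates to one on quadrature grids to better than 1%.

## Mode seeking

Each point starts a safeguarded ascent: the full Newton step is taken
when the Hessian is negative definite and the step points uphill,
otherwise steepest ascent, with backtracking so the density never
decreases over accepted iterates. Steps are capped at 3 kernel lengths —
the Mahalanobis norm of the step under the (broadened) pilot covariance —
and the steepest-ascent fallback at 1 kernel length. The cap is the
load-bearing safeguard: an unbounded Newton step from a fringe point can
jump clear across an inter-cluster valley onto a higher, unrelated peak,
and a Euclidean cap fails for anisotropic kernels, where three long-axis
standard deviations may be dozens of short-axis ones. Climbs converge
when the gradient norm falls below 1e−8 (at most 200 iterations); a climb
ending at a non-concave stationary point is treated as non-converged and
its point is assigned to the located maximum minimizing
distance/density. Converged endpoints within 1e−3 of each other are the
same maximum. Maxima are labeled by decreasing peak density, ties broken
lexicographically by location, so results are deterministic.

## Saddle search and merging

The merging matrix M holds peak densities on the diagonal and the density
of the located first-order saddle between each adjacent pair off it.
Saddle searches for a pair (a, b) start from the centroids of the 5
closest cross-cluster point pairs. A search is abandoned when the density
falls below 1e−4 of the tallest peak (a scale-free floor) or when a third
cluster's kernel weight at the iterate exceeds the combined weight of a
and b — in both cases the pair is judged not directly connected and
contributes zero. The combined-weight reading matters in practice: a
per-cluster reading aborts legitimate searches between interleaved
fragments of one structure (e.g. neighboring segments of a noisy ring)
whose joint weight clearly dominates any third fragment.

Each search has three phases. (1) A bounded 1-D minimization of the
density along the line joining the two maxima, restricted to the stretch
between them. (2) A safeguarded ascent restricted to the hyperplane
orthogonal to that line (a ridge climb). Phases 1 and 2 alternate four
times and bracket the mountain pass. (3) A Newton polish by eigenvector
following: in the Hessian eigenbasis, the eigendirection with the largest
overlap with the inter-maxima axis — the pass direction at the saddle —
has its eigenvalue and gradient component flipped, making the saddle a
stable maximum of an implicit surrogate whose derivatives are available
without constructing the surrogate itself. Where the flipped Hessian is
negative definite the plain Newton step is taken (flipping both the
eigenvalue and the gradient component leaves the Newton step unchanged,
so the flip convention is a safeguarding choice, not a different method);
elsewhere an eigenvalue shift keeps the step ascending the surrogate. A
converged endpoint counts only if its Hessian has exactly one positive
eigenvalue (first-order signature). If the polish leaves the pass region
or fails to converge — systematic on strongly curved ridges such as
rings — the bracketed point from phases 1–2 is accepted instead, provided
it is near-stationary (gradient times kernel scale below 5% of the
density) and index-1. The largest valid saddle over the five starts
enters M, capped at the lower of the two peaks.

Merging is greedy: while some pair has μ_ab = M_ab/min(M_aa, M_bb) above
β, the highest-μ pair merges, both its diagonals become max(M_aa, M_bb),
and the off-diagonal is zeroed — the diagonal raise is what stops a
low-density cluster from indirectly linking two high peaks. β defaults to
1/e; raising it fractures clusters, lowering it merges more, and the
executed μ values form a non-increasing sequence.

One post-pass handles an edge case the abort rule creates: a small
satellite maximum riding on a large cluster's flank can have *every* one
of its saddle searches cut off because the parent cloud's other fragments
dominate its entire surroundings, leaving a spurious 1–3-point cluster.
After the merge loop, a group none of whose searches located a pass, at
least one of which was cut off by members of one particular target group,
and whose target carries at least floor-level density at the orphan's own
summit, is assigned to that target. The three conditions are all needed:
a located-but-low pass (μ ≤ β) marks a genuine neighbor boundary and
blocks absorption; domination evidence alone would absorb clusters hidden
behind an unrelated cluster; and the summit-density check keeps apart
structures separated by genuinely empty space (concentric rings, distant
mixture components), because the target has no mass there.

Outliers: with γ > 0, point i of final cluster c is flagged when
f̂(Yᵢ)/M_cc < γ. Flags never change labels; γ = 0 (default) flags
nothing.

## Warm restarts

The optimized covariance does not depend on the broadening α, so changing
α restarts at the maxima search with the stored C and Abramson factors;
changing β re-runs only the merge loop and absorption from the stored
matrix; changing γ recomputes flags from stored densities. Warm results
are bit-identical to cold runs at the same parameters (tested).

## Evaluation metrics

Homogeneity h = 1 − H(class|cluster)/H(class), completeness
c = 1 − H(cluster|class)/H(cluster), V-measure 2hc/(h+c), with entropies
from the class-by-cluster contingency table, 0·log 0 = 0, and the
conventions h = 1 when H(class) = 0 and c = 1 when H(cluster) = 0.
Natural logarithms; the scores are ratios, so the base cancels. Flagged
outliers are scored under their assigned label (flags are metadata). The
implementation agrees with an independent reference implementation to
1e−10 on random label pairs (tested).

## Synthetic benchmarks

The generators are seeded and deterministic, and their defaults are the
study conditions:

- **blobs** — three unit-variance Gaussian clusters at the conventional
  center layout (drawn uniform in [−10, 10]² by the standard toy
  generator with its widely used seed, here fixed as constants), all
  sheared by [[0.6, −0.6], [−0.4, 0.8]]; two sheared centers are close
  together. Probes anisotropy not aligned with the feature axes.
- **varied** — isotropic Gaussians with standard deviations 1.0, 2.5 and
  0.5 at the same centers. Probes density contrast and overlap.
- **circles** — two concentric rings, radii 1 and 0.5, points evenly
  spaced in angle (random phase) with radial Gaussian noise of standard
  deviation 0.03. Even spacing is the conventional construction; random
  angles would add Poisson gaps along the rings that dominate the
  difficulty. Probes concave clusters.
- **simplex** — D+1 isotropic Gaussian clusters of 100 points at the
  vertices of the standard unit D-simplex (the one spanned by the unit
  basis vectors; edge length √2, overridable). σ = 0.1 gives no overlap,
  0.2 slight, 0.3 heavy.

The trajectory generator emulates a branching photochemical ensemble:
smooth template paths in (wing separation, rhombicity, wing length) that
bifurcate at given times — rhombicity splitting to ±0.8 Å near 35 fs,
wing separation splitting into reactant-like recovery versus product-like
compression near 55 fs — realized as planar four-atom geometries whose
pairwise distances reproduce the requested features exactly (a sheared
trapezoid with a closed-form shear). Trajectory noise is a constant
Gaussian offset per trajectory and feature plus small frame-to-frame
jitter (one tenth of the offset scale). What this does not emulate:
curvature of real internal-coordinate manifolds, heteroscedastic noise
growth along the dynamics, trajectories leaving and re-entering clusters,
and any electronic-state information. Passing the channel-recovery tests
therefore shows the pipeline separates well-defined feature-space
branches at realistic noise, not that it resolves every ambiguity of a
real surface-hopping ensemble.

## Per-frame trajectory pipeline

Features and their central-difference rates form a six-column matrix per
frame (one-sided differences at the ends; velocity-based rates would need
inputs the feature definition does not include). Each clustered frame is
independently reduced by PCA — plain eigendecomposition of the covariance
of the mean-centered columns, no whitening or standardization — keeping
the components with explained-variance ratio above 1% (at least one).
The [0, 1] normalization happens afterwards, inside the clustering, which
is legitimate because the pipeline is scale-independent; normalizing last
keeps the core self-contained. Rhombicity is kept signed: the dynamics
are symmetric about zero rhombicity and the sign carries which branch a
trajectory took. Clustering runs every 5 fs by default. A frame where all
trajectories coincide (zero variance) is a single cluster by definition
and skips the pipeline. Channels are the distinct tuples of cluster
labels over the checkpoint frames (defaults 40, 50, 70 fs), reported with
member counts; trajectories that are spatially alike but time-shifted
fall into different channels because their labels differ at checkpoints
between the two transition times.

## Problem sizes and limitations

The implementation is exact — no tree or grid acceleration — with
covariance optimization costing O(N²D) per sweep and the mode search
O(N²D²) per climb sweep, which is comfortable for the intended N ≤ 1000;
the bundled tests and the reproduction script run the full benchmark grid
(up to 800 points in 7 dimensions) on one CPU in minutes. Known
limitations: KDEs on a few hundred points in D ≥ 6 are intrinsically
spiky, so occasional small satellite clusters survive even after
absorption (visible as completeness slightly below 1 at D = 6–7); scores
on the overlapping-cluster benchmarks fluctuate across seeds, and for
unlucky samples a genuine pass with μ > 1/e exists between two
generating clusters, which the merge rule then (correctly, by its own
criterion) merges; periodic/angular features are not supported — kernels
are plain Gaussians with no minimum-image convention.
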