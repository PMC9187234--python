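# Methods

## The objects

A vessel network is a spatial graph: nodes with 3D coordinates in
micrometers (branching points plus sample points along vessels), edges for
the vessel pieces connecting them, and a *segment decomposition* — maximal
vessel paths between branching points and/or endpoints. Segments are the
normalization unit for every per-segment descriptor, so the decomposition
is a maintained invariant (every edge belongs to exactly one segment;
node kind follows graph degree). A component that is a pure cycle is stored
as a single closed segment anchored at its smallest node id.

## Filtrations

**Radial filtration.** The tumor center is approximated by the center of
mass of the network nodes (unweighted mean). The maximal node distance to
the center, `r_max`, is divided into `n_steps` uniform radii (default 500).
A node enters at the smallest grid radius greater than or equal to its
distance — i.e. it snaps *up*, and a node exactly on a grid radius enters
at that radius; an edge enters as soon as both endpoints are inside the
sphere. The filtration contains only nodes and edges, never filled
triangles, so its homology is dimension 0 (connected components) and
dimension 1 (loops), and loops never die: every dimension-1 class is
essential and closes at the final radius. Internally the filtration stores
integer step indices rather than floating radii, so ties between steps are
exact and results are bit-reproducible. With 500 discrete steps, features
narrower than one step (about 0.2% of `r_max`) can be stepped over; this
is a deliberate resolution/feasibility trade-off and the step count is
configurable.

**Alpha-complex filtration.** On the 3D node cloud the Delaunay
triangulation is computed (scipy/Qhull); each tetrahedron carries the
square of its circumradius as filtration value; each triangle or edge
carries its own squared circumradius when its circumsphere contains no
other vertex, and otherwise the minimum value of its cofaces, assigned
inductively from tetrahedra downward. Vertices enter at 0. The effect is
that, e.g., the long edge of a slim triangle only enters together with the
triangle, which prevents spurious cycles. Dimension-2 classes of this
filtration are the avascular voids; the filtration value has units of
square micrometers and is a proxy for void volume.

Numerical choices: circumcenters are found by an exact linear solve in the
simplex's affine hull; a solve whose residual exceeds `1e-8` relative is
treated as degenerate and the simplex falls back to the inductive
coface-minimum rule. Assigned values are additionally clipped to the
coface minimum so face-monotonicity holds exactly. Emptiness of a
circumsphere is tested with a relative tolerance of `1e-9` of the squared
bounding-box diagonal. Degenerate inputs (coplanar or lattice-like
co-spherical clouds) are rejected with advice to apply
`jitter_points` — a deterministic jitter of `1e-6` times the bounding-box
diagonal under a fixed seed.

## Persistence

Graph filtrations use a union-find sweep: each node births a dimension-0
class at its entry step; an edge merging two components kills the younger
one (elder rule; equal births are resolved in favor of the smaller
union-find root id, which makes output deterministic under node
relabeling); an edge joining an already-connected pair births an essential
dimension-1 class. Conservation laws hold exactly: one dimension-0 bar per
node, one essential dimension-0 bar per final component, and
`E - V + C` dimension-1 bars.

Simplicial filtrations use standard boundary-matrix column reduction over
the two-element field with sparse set-valued columns and a pivot cache.
Intervals follow the half-open `[b, d)` convention; essential classes
record the final filtration value as death and carry an explicit flag.
Zero-persistence bars are retained by the engine (they are needed for the
conservation laws) and filtered downstream where appropriate.

The test oracle is independent of the pairing logic: `oracle_betti` builds
the sub-complex at a value, assembles dense boundary matrices and computes
Betti numbers by direct rank computation over the two-element field;
`betti_curve_bruteforce` evaluates the same ranks at every filtration value
with one incremental elimination pass per dimension so whole-filtration
batteries stay fast. For graph filtrations the oracle is connected-component
counting and the cycle-rank formula on the restricted subgraph.

## Descriptors

* **Topological tortuosity** = (number of dimension-0 bars with persistence
  <= `short_fraction * r_max`) / (number of vessel segments), default
  `short_fraction = 0.1`, comparison inclusive. Zero-persistence bars are
  *excluded* by default: under the half-open convention `[b, b)` is empty,
  and counting such bars would score a perfectly straight radially-sampled
  vessel as maximally tortuous (every sample node enters and merges at the
  same step). The `include_zero_bars` switch restores the other convention.
  The per-segment normalization makes the descriptor invariant under
  disjoint-union doubling of a network (verified exactly in the tests).
* **Loops per segment** = dimension-1 bar count / segment count. The
  segment count is taken from the same network the filtration was built on
  (if branches were subsampled first, both numerator and denominator see
  the subsampled network).
* **Void descriptor** = median persistence of dimension-2 bars of the alpha
  filtration, in square micrometers. Bars with persistence below `1e-9`
  of the final value are numerical artifacts of nearly co-spherical points
  and are dropped before the median; an empty barcode scores 0 with a
  warning.
* **clr** = endpoint chord distance / path length per segment, in (0, 1];
  closed segments score 0. Network-level value: unweighted mean over
  segments.
* **SOAM**: the segment polyline is resampled at uniform arc length
  (default step: the median inter-node spacing of the segment) and the
  angles between consecutive chord tangents are summed, reported in
  degrees, with a per-length variant in degrees/um. The raw angle sum is
  the primary field; the torsional (out-of-plane) component of the
  original formulation is deliberately omitted — only in-plane turning
  between consecutive tangents is summed.

## Preprocessing

* Anisotropy correction: `rescale_z` multiplies z coordinates by a given
  factor (0.835 is the standard value for the intravital imaging geometry
  this pipeline targets).
* Branch subsampling: `subsample_branches(net, k)` keeps all branching
  points and endpoints and every k-th interior node per segment (1-based,
  counted from the lower-id terminus, so results are reproducible under
  relabeling). k=2 and k=4 are the conventional choices for dense
  intravital and whole-tumor stacks respectively. Collapses that would
  create a parallel edge keep the middle interior node, and closed
  segments always keep at least two interior nodes, so component count and
  cycle rank are preserved exactly.
* Skeleton extraction uses 26-connectivity. Two topology-preserving
  cleanups are applied: the longest edge of every 3-cycle of the voxel
  adjacency graph is removed (26-adjacency of rasterized lines creates
  spurious triangles at corners), and mutually adjacent branching voxels
  are collapsed to a single branching node at their centroid (thick
  junctions otherwise shed micro-segments). Skeletons with many
  high-neighbor-count voxels are accepted but flagged in the log as thick.
  Pruning of short spurious spurs is assumed to have happened upstream in
  the skeletonization pipeline and is not re-implemented here.

## Synthetic data

The generators produce networks and point clouds whose topology is known
by construction: straight/sinusoid/helix vessels (single segment, no
loops), trees, planar loop grids (cycle rank `(nx-1)(ny-1)`), rings,
Fibonacci-sphere shells joined by 6-nearest-neighbor edges (one enclosed
cavity; two for nested shells), torus surface clouds (two independent
loops, one void), bounded-turning random walks, and "loopy" networks —
radial spokes with small rings welded at chosen radii, giving exact loop
counts with controllable birth radii. `make_cohort` builds longitudinal
treatment groups from loopy networks: loop density rises toward 1+effect
times baseline in a sprouting-up group, falls symmetrically in a
sprouting-down group, stays flat in controls, with a 10% coefficient of
variation on realized loop counts (count-like descriptors carry small
measurement noise); the peripheral variant places the added loops in the
outer 70–90% radial band. Default effect size is +50% at the final
observation day with 5 subjects per group — a deliberately
detectable-but-not-trivial regime for the nonparametric battery.

What the fixtures emulate — and what they do not: they reproduce the
geometry and topology regimes of real vessel networks (tortuosity levels,
loop densities, enclosed cavities, anisotropic sampling) but not
segmentation noise, gaps, spurious spurs, diameter variation along
vessels, or the sheer size of whole-tumor reconstructions. Passing tests
therefore demonstrate correctness of the computational pipeline on
well-posed inputs, not robustness to segmentation failure modes.

Helix fixtures used in the tortuosity tests place the filtration center
2000 um from the coil axis: a coil's distance to a far center oscillates
once per turn, so the sphere sweep sheds one short component per turn and
the short-bar count tracks the turn count — the geometric mechanism the
descriptor is designed to capture. With the center on the helix axis the
distance is monotone along the vessel and no short bars arise.

Voxel round-trip guarantees hold for line-like fixtures whose feature size
exceeds ~3 voxels. Surface-like shells are excluded by construction (their
mesh cells are below that threshold), as are loopy networks (the weld
between ring and spoke is tangential, i.e. locally sub-voxel).

## Statistics

Group comparisons: Kruskal-Wallis across all groups, then pairwise
two-sided Wilcoxon rank-sum tests against the control group at level 0.05
without multiple-testing correction; exact p-values are used for small
tie-free samples (scipy switches to the exact method automatically below
9 observations per group), and an independent full-enumeration oracle
validates them for n <= 6. Because the rank-sum test is discrete, its
attainable size at small n sits below the nominal 0.05; the calibration
check therefore simulates null cohorts with 20 observations per group
(attainable size within ~0.003 of nominal) and allows 0.02 slack =
discreteness + three binomial standard errors at 2000 replicates.

Correlation structure: pairwise Pearson correlations between descriptor
columns; rows of the correlation matrix are clustered by complete linkage
under the Euclidean distance, with columns sorted by name beforehand so
leaf order is deterministic under ties.

Shell profiles: loops are binned by birth radius (the only radial
coordinate a dimension-1 bar has, as all loop deaths sit at the final
radius), divided by that day's segment count, medianed across tumors, and
normalized per shell by the day-0 value. Zero or missing baselines yield
flagged-undefined cells, never infinities. Default shells are 10
equal-width annuli of each filtration's own maximal radius (relative
mode), which keeps shells comparable across days with different extents;
a fixed-width absolute mode is available when a common spatial frame is
preferred. Whether the median should be taken across tumors after the
per-tumor normalization (the default here) or within tumors first is a
genuinely open convention; both orders are computable from the same
inputs.

## Known limitations

* The radial filtration assumes an approximately spherical growth
  geometry; strongly ellipsoidal tumors would motivate an ellipsoidal
  sweep, which is not implemented.
* The center-of-mass center is an approximation; descriptors aggregated
  over wide radial intervals are insensitive to small center shifts, but
  single-shell values near the center are not.
* Alpha filtrations on noisy samples legitimately assign enormous values
  to near-flat hull slivers; top-persistence rankings of small features
  are therefore less stable than mid-scale Betti counts, and the torus
  fixture is validated at mid-scale for exactly this reason.
* Persistence is computed with correctness, not throughput, as the
  contract; whole-tumor clouds (10^5+ nodes) would need a specialized
  reduction backend upstream of the descriptor layer.
* No vectorized barcode transforms (persistence images/landscapes),
  no bottleneck/Wasserstein distances, no homology above dimension 2.
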