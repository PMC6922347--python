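# Methods

`conduitmap` turns a 3D grayscale volume of a fine tubular network — the
lymph-node conduit system imaged at ~1 µm isotropic voxels is the motivating
case — into a cleaned graph ("topology map"), computes quantitative network
statistics including a deep-vs-superficial zone comparison, and simulates
T-cell motility constrained to the network. Because no public volume of this
kind exists, a synthetic phantom generator with exact ground truth is a
first-class part of the package; every pipeline stage is validated against
it.

## Image preprocessing

**Z-equalization.** Block-face stacks show plane-to-plane intensity
fluctuation. For each plane the average intensity `A(z)` of pixels above a
noise threshold is computed, smoothed along z into `SA(z)` (centered moving
average, default window 21 planes, edge-truncated), and each plane is scaled
by

```
f(z) = a·SA(z)/A(z) + (1 − a),     a = 0.9 by default
```

then clamped to [0, 255]. The weight `a < 1` prevents over-correction;
planes with no signal get `f = 1`. The correction removes variation faster
than the smoothing window; slower trends (e.g. the changing cross-section of
a spherical sample) are part of `SA` and deliberately preserved.

**Segmentation.** Local mean thresholding: a voxel is foreground iff its
intensity exceeds the mean over a cubic window (default 25 µm) plus an
absolute offset (default 50 intensity units). Local thresholding keeps dim
fine tubes next to bright thick ones. Both parameters are config-overridable;
no universal values exist for real stacks.

**Vessel exclusion.** Conduit sleeves around blood vessels are hollow tubes
that thinning cannot reduce to a centerline. The vessel channel is segmented
the same way, dilated by a Euclidean distance (default: sleeve thickness),
and subtracted from the conduit mask; alternatively the two masks can be
unioned so vessels become solid, traceable tubes.

**Largest component.** Only the largest 26-connected foreground object is
skeletonized (ties broken toward the lowest label in scan order).

## Skeletonization and tracing

Thinning uses the 3D topology-preserving algorithm from scikit-image, with
an engineering workaround for a failure mode of that implementation: tube
runs whose digital cross section is even-width in every direction get
deleted outright (a 2-voxel-wide bar — exactly the width of a 2.9 µm tube
at 1 µm voxels — vanishes entirely, and surface bumps do not protect it
because they are thinned away first). Two measures address this. First,
the mask is resampled ×3 by trilinear interpolation (threshold 0.4, which
keeps diagonally-connected chains connected) and padded by a one-sided
single-voxel dilation before thinning; the smooth surface also suppresses
the staircase barbs and ladder loops thinning produces on jagged digital
tubes. Second, a coverage check catches any run the parity accident still
erases: mask voxels farther from the skeleton than 1.4× the local tube
radius (+3 fine voxels), and not near a skeleton endpoint (rounded caps
legitimately extend about one radius beyond the tip), mark regions that are
re-thinned with an extra parity-flipping dilation, for up to three
alternating rounds. The skeleton is returned on the fine grid (voxel/3)
and its centerline may sit within half a source voxel of the strict mask
surface; tiny disconnected fragments left by cap patches (total length
below the voxel-scale floor) are dropped during tracing.

Tracing classifies skeleton voxels by their 26-neighbor count: voxels with
≠2 neighbors are vertex material. Maximal connected clusters of junction
voxels collapse to a single vertex at their centroid (sub-resolution
junction geometry otherwise inflates branch counts), degree-2 chains become
centerline polylines, and closed rings with no junction become a self-loop
on an anchor vertex. Two cleanup passes remove artifacts below the
resolution of the voxel grid: terminal barbs shorter than 1 µm and
junction-to-junction bridges shorter than 1 µm (contracted). Polylines are
smoothed with a 3-point moving average (endpoints fixed, two passes) before
any length or angle is measured, countering voxel jitter.

**Radius estimation.** The per-point radius comes from the Euclidean
distance transform of the mask sampled at centerline voxels. The raw EDT at
a slightly off-axis digital centerline systematically underestimates the
radius of tubes whose surface detail is below one voxel; the affine
calibration `r = 1.25·EDT + 0.14·voxel`, fitted on noise-free
constant-radius tube renderings (radii 0.75–2 voxels, random orientations
and sub-voxel offsets), recovers radii to ~0.05 voxel. An edge's diameter is
twice the mean radius over its polyline points.

## Graph cleanup

**Healing** (default bound 15 µm) resolves short dead ends before
simulation: each degree-1 vertex whose incident edge is ≤ the bound is
joined by a straight edge to the nearest other vertex within the bound
(Euclidean; join is preferred because it preserves connectivity for
walkers), or pruned when no target exists. The pass iterates until no
eligible dead end remains. Joins and prunes are logged in the network
metadata.

**Cropping** to a spherical subregion (default diameter 100 µm) keeps
polyline points inside the sphere; edges crossing the boundary are cut at
the last interior point, which becomes a vertex marked as a boundary
artifact and excluded from degree statistics (a cut is not a biological
tip).

**Shrinkage correction** multiplies all coordinates by 1.25 — the inverse
of the ~20% per-axis tissue shrinkage of resin embedding — leaving radii
untouched; double application is refused.

## Network statistics

* Segment stats: counts, per-edge lengths and mean diameters, conduit
  volume Σ π(d/2)²·L, degree histogram (self-loops count twice), and
  segment density when a region volume is supplied.
* Branching angles: at every vertex of degree ≥ 3, pairwise angles between
  arc-local direction chords (unit vector from the vertex to the point 5 µm
  along each edge); edges shorter than 4 µm are skipped to avoid the jitter
  of very short traced segments.
* Orientation: each edge's end-to-end vector projects onto 13 reference
  axes (3 coordinate axes, 6 face diagonals, 4 body diagonals — the lines
  from a grid point to its 26 neighbors); summed projection magnitudes are
  normalized to 1. The measure is invariant to subdividing edges.
* Distance field: per-voxel Euclidean distance to the nearest conduit
  voxel, with summary fractions below 4/6/8 µm and the mean, evaluated over
  an optional mask. Distances are measured to the segmented mask surface,
  not to centerlines.
* Density field: mean foreground fraction in a cube of half-width 10 µm
  sliding in 2 µm steps, rescaled 0–1 → 0–255 (ties round to even).
* Zone comparison: per-subregion metric tables for the deep (central
  sphere) and superficial (shell) zones compared by unpaired two-tailed
  Student t tests, starred at the usual thresholds. A helper proposes
  non-overlapping subregion centers by greedy maximin placement, since five
  100 µm spheres inside a 130 µm-radius deep zone are close to a packing
  and defeat plain rejection sampling.

## Motility simulation

Cells walk on the healed network. Each of N cells (default 5,000) draws a
speed once from a Gaussian (mean 13 µm/min, CV 0.1, redrawn if ≤ 0), starts
at a polyline point chosen uniformly inside a start sphere (default radius
100 µm at the domain center) with a random initial direction, and advances
at constant speed along the centerlines for 60 min. At a junction the
turning angle θ(k) to each candidate branch is computed from 5 µm direction
chords, and the branch is sampled with weight cos⁴θ when cosθ > 0 and a
floor of 0.001 otherwise. Degree-2 vertices are pass-throughs; dead ends
reverse the direction of travel. Positions are recorded every 5 min. Each
cell owns a counter-derived random substream, so results are independent of
scheduling and exactly reproducible from one seed.

The coefficient of motility is the diffusion-like index

```
Cm = MSD(T) / (6 T),   T = 60 min,
```

the mean squared displacement of the population from its start points at
the final time divided by 6T (the average slope of the MSD curve between 0
and T). On a junction-free straight path this reduces to v²T/6 exactly,
which the tests assert. A deliberately naive stepwise walker, kept in the
test suite and sharing no code with the engine, reproduces the engine's MSD
curve within Monte-Carlo error.

## The phantom generator

The generator grows a connected geometric graph with the statistical
structure the analysis assumes, then rasterizes it.

*What it emulates:* a spherical node (default radius 400 µm) whose deep
central sphere (radius 200 µm) holds half the segment density of the
superficial shell; segments with lognormal lengths (mean 6.5 µm, SD 3 µm)
and truncated-normal diameters (mean 2.9 µm, SD 0.6 µm, minimum 0.5 µm);
predominantly trifunctional junctions with branching angles near 120°; a
sparse forest of thick vessels (log-uniform diameters 4–87 µm) optionally
wrapped in hollow conduit-labeled sleeves (thickness 2 µm); 8-bit images
with foreground 200, multiplicative sinusoidal z-modulation, and additive
Gaussian noise.

*Growth model.* Active tips extend curved polyline segments in 2 µm steps
(per-step heading jitter ~4°, deflection capped at 25° so collision
avoidance cannot kink a tube — kinked tubes rasterize into shapes whose
medial axis spuriously branches). A segment runs junction-to-junction: when
its drawn length is reached the tip branches into two daughters at ±60°
from the running direction, giving three ~120° angles at the vertex.
Candidate steps are rejected when they would bring the tube surface closer
than a minimum clearance (default 1.5 µm) to any non-adjacent segment; the
real conduit mesh does not self-intersect, and without this constraint
rasterized tubes fuse at realistic densities. Edges meeting at a vertex may
share space within ~6 µm of it (junction geometry is real). Disconnected
trees are stitched into one component by short straight connectors that
prefer clearance-respecting paths.

*Density control.* Segment quotas are allocated on a cubic grid of cells a
few mean segment lengths wide (segment midpoints decide the cell), with
quotas stochastically rounded so small cells carry no bias. Branching
growth is a cluster process whose free-running density fluctuations at the
100 µm scale would swamp a twofold zone contrast; per-cell caps bound those
fluctuations at the cell scale. Unfillable sliver cells are abandoned after
repeated re-seeding rather than looping forever, and a spec whose density
cannot be packed at all raises an explicit error (packing-fraction check at
validation plus a stall guard during growth).

*Calibration constants.* Three internal constants keep realized statistics
on the nominal values under collision-limited growth, all fitted on the
generator's own geometry before any downstream comparison: the length-draw
mean is deflated to 0.73 of nominal (a tip whose second daughter fails to
grow continues as the same segment, inflating junction-to-junction
lengths); raw cell quotas are inflated by 1.12 (pass-through contraction at
the end merges ~12% of raw segments); and length draws below 1.2 tube
diameters are resampled, since junction spacing below the tube's own width
is neither meaningful nor resolvable geometry. Realized statistics at the
default density, across seeds: density within ~±5%, mean length within
~±10% of nominal, mean diameter essentially exact; per-zone densities land
within the generator's ±15% contract.

*What the phantom does not emulate:* follicular reservoirs, medullary
sinuses, capsule geometry, stromal cell bodies, staining heterogeneity,
anisotropic point-spread blur, or mosaic stitching artifacts. Passing the
phantom round-trip therefore demonstrates correctness of the geometry
pipeline, not robustness to every artifact of real acquisitions.

## Problem sizes

The validation suite runs at desk scale by design: the extraction
round-trip uses a ~450-segment phantom at full density (domain radius
32.3 µm, 1 µm voxels, noise SD 10); the zone comparison uses a ~24,000
segment two-zone graph (domain radius 250 µm, densities 2·10⁵ and 4·10⁵
segments/mm³ — a scaled-down density pair that preserves the twofold
contrast while keeping generation tractable); simulator cross-checks use
5,000 cells on a ~50-edge network. The same code paths run unchanged on
larger volumes.

## Known limitations

* Terminal segments shorter than about one tube diameter plus the cap
  erosion of thinning (~1.5 radii) are not recoverable from 1 µm images;
  the generator consequently does not produce sub-diameter stubs.
* The radius calibration is fitted for the default ×3 thinning resample;
  other upsample factors shift the EDT bias slightly.
* Healing joins by Euclidean (not along-network) proximity, matching the
  cleanup's purpose of giving walkers an exit from dead ends.
* `Cm` on small phantoms is confinement-limited once RMS displacement
  approaches the domain radius; domain ≳ start radius + RMS displacement
  is the caller's responsibility.
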