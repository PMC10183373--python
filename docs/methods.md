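# Methods

This note documents the model, the numerical choices and their
rationale, what the synthetic data does and does not emulate, and the
known limitations. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Coordinates and data model

Volumes are arrays indexed `(z, y, x)` (TIFF page order) with positive
per-axis spacing in µm; the centre of voxel `(k, j, i)` sits at
`origin + (k·sz, j·sy, i·sx)`. Meshes live in the same physical
coordinates, so meshes and images at different resolutions compose
freely. A segmentation mesh is a closed, genus-0, outward-wound triangle
surface; closedness (every edge shared by exactly two faces), Euler
characteristic 2 and positive signed volume are checked after every
topology-editing operation.

## Image energies and forces

One "pixel" is the smallest spacing component; stencil offsets are unit
pixels along the node normal, with trilinear interpolation clamped at
the volume border (clamping avoids spurious edge forces where a mesh
approaches the boundary of the grid).

The Gaussian-derivative stencil is
`k_i = −i/(√(2π)σ³)·exp(−i²/(2σ²))`, σ = 2 px, half-width w = 5 —
values chosen to smooth noisy intensity profiles at low cost. Because
every force and energy normalises by `Σ|k_i|`, only the stencil's shape
matters; any positive prefactor cancels. The stencil is applied in
convolution orientation (offset −i pairs with `k_i`), so its response is
the *positive* directional derivative of the Gaussian-smoothed profile:
with `w_img > 0` the intensity force climbs toward bright structure, and
with `w_img < 0` it descends — the orientation needed for both membrane
attraction and distance-transform wrapping, and fixed by those
behavioural requirements. The gradient-energy force and the
mean-intensity energy use the printed normalisations (`Σ|k_i|` and
`Σ G(u)` respectively); these differ by the fixed constant
`ρ = σ²·ΣG/Σ|i|G ≈ 2.60` at the defaults, which in practice is absorbed
into `w_img`. The mean-intensity energy truncates the Gaussian at the
same half-width w and normalises over the truncated discrete kernel.

Intrinsic forces are `−α·L(x) − β·L²(x)` with L the uniform graph
Laplacian (`L(x)_v = x_v − mean of neighbours`). This is the standard
discrete area/bending penalty pair; on a convex mesh `L(x)` points
outward, so positive α shrinks and smooths. The uniform Laplacian was
chosen over cotangent weights for robustness on the near-uniform
triangulations the remesher maintains.

## Mesh evolution

Explicit-Euler updates `x ← x + step·F`, with each vertex displacement
capped at 0.5 px per iteration for stability. Convergence is declared
when the maximum vertex displacement stays below `tol = 0.01 µm` for 10
consecutive iterations; `max_iters` bounds the loop. Every 50 iterations
the mesh is remeshed to edge lengths in [1, 3] px (iterative
longest-edge bisection, link-condition edge collapse, tangential
Laplacian relaxation, volume restored by a centric rescale; enclosed
volume changes < 2%). Stability requires `step·α·λ_max(L) < 2` with
`λ_max ≤ 2`; the defaults keep this product well below 1 — at the
boundary the Laplacian term oscillates neutrally and never converges.

Meshes that find no steady state shrink under α; results with volume
below `v_min` (default: a 1.5 µm-radius ball) are removed. This doubles
as the false-positive filter for spurious seeds.

Defaults: for raw-intensity work (`gradient` mode on images normalised
to [0, 1]) `α = 0.05, β = 0.01, w_img = 60, step = 0.1` — the large
weight simply saturates the per-step cap far from the target and hands
control to the cap; the equilibrium is set by the energy's zero
crossing, so recovery is insensitive to `w_img` over at least a 4×
range. For distance-transform work the seeding defaults are
`α = 3.0/h, β = 0.05/h, w_img = −1, step = 0.125·h` (nuclei) and
`α = 2.5/h` (membranes), where `h` is the pixel size in µm: the
distance transform rises one count per *pixel* while the Laplacian is
*physical*, so expressing α per pixel makes the image/shrink balance —
and hence the sub-voxel position of the steady state — independent of
resolution. Seed meshes are remeshed to the target edge range *before*
evolving; otherwise the shrink pressure would depend on the seed's
triangle sizes and hence on object shape.

Known limitation: the shrink force scales as `l²/R` (edge length l,
local radius R), so the equilibrium drifts outward by 1–2 px as objects
grow. The defaults are tuned for the phantom regime (nuclei ~10 px,
cells ~15 px radius); for much larger objects α should be raised — the
classical "positive and sufficiently large" area penalty.

## Labels and losses

From a set of closed meshes: `mask` = union of voxel centres inside any
mesh (scanline x-ray parity with a fixed symbolic perturbation, so
voxelization is deterministic and watertight); `border` = mask voxels
with a 6-connected outside neighbour (the array boundary counts as
outside); `dt` = erosion depth, i.e. the iteration at which 6-connected
peeling removes the voxel (border depth 0), saturated at 32. The depth
is computed as the taxicab chamfer distance to the outside minus one —
identical to iterated erosion, in linear time; the test suite checks
voxel-for-voxel agreement against an explicit erosion loop. 6-connected
erosion is the most conservative reading of "eroding in 3D"; component
labelling of seed cores uses 26-connectivity (the more permissive
grouping for a single core) — a deliberate asymmetry.

Touching instances are voxelized jointly (union); separating them is
the seeding stage's job via the distance-transform ridge. The Dice
losses use the plugin form `(|T∩P|+1)/(|T|+|P|+1)` with soft
intersection, exactly as printed; the conventional
`1 − 2|T∩P|/(|T|+|P|)` is available behind a flag. The
distance-transform loss is `log(mean((T−P)²)+1e-8)` — mean inside the
log, the only reading that is finite on typical batches; the epsilon
guards the perfect match. Default weights are (1, 1, 1).

## Seeding and instance segmentation

Threshold semantics are `dt ≥ θ` with θ = 3 by default: θ = 1 means
"strictly interior", and 3 erosion depths separate cores of nuclei
whose interiors a single erosion would leave connected. Components are
size-filtered (lower bound: a 1 µm-radius ball in voxels). Growth is a
marker-controlled watershed on `−dt` over the domain `dt ≥ 1` (growing
only over strictly-interior voxels; ties resolve to the lower label),
chosen over plain region growing for its deterministic partition.
Raycast initialisation marches each ray at a quarter of the smallest
spacing and places the vertex at the centre of the farthest region
voxel hit, which puts the seed surface about half a voxel inside the
region — the subsequent deformation corrects this.

Membrane meshes copy the nucleus meshes (inheriting instance ids), are
coarsened to [1.5, 4.5] px edges (cell surfaces are larger and
smoother; the coarser mesh keeps contact bookkeeping cheap) and evolve
in lockstep. Mutual exclusion uses a shared voxel-occupancy grid (each
mesh rasterized and dilated by one voxel, refreshed every other
iteration): a vertex may not step onto a voxel owned by another mesh,
so contacts settle deterministically with a small safety gap instead of
oscillating; genuinely penetrating vertices (e.g. overlapping inputs)
additionally feel an exact repulsion along their reversed normal,
proportional to a penetration-depth estimate. Cells crushed by their
neighbours stop evolving and fall to the small-volume filter.

## Detection, evaluation, tracking

Volumetric best JI is computed from a sparse contingency table
(equivalent to all-pairs intersection counting; argmax ties to the
lower predicted label); ΔCM uses unweighted voxel-centre means in
physical units. Detection maps each prediction to its highest-bbox-JI
ground truth and vice versa; mutual single pairs are TP, multiple
predictions on one ground truth are FP, everything else on the
ground-truth side is FN; zero-JI mappings count as unmapped, so
disjoint sets produce no FP. Box JI and volumetric JI are never
conflated. Tracking is greedy frame-to-frame linking by maximal box JI
above 0.1; a track that disappears while overlapping the first boxes of
two or more newborn tracks records them as children (division
candidate).

## Synthetic data

The phantom emulates: ~10 cells per aggregate, nuclei of ~8 µm diameter
as randomly oriented ellipsoids (axis ratio ≤ 1.5, sampled up to 1.3 by
default, so meshes must genuinely deform), cells as the Voronoi
partition of a 17 µm ball on a 128³ grid of 0.35 µm voxels (the
half-resolution imaging regime), membrane shells two voxels thick on
cell-cell and cell-exterior boundaries, Gaussian PSF blur (σ = 1 px),
mild Gaussian read noise (sd 0.02) with optional Poisson shot noise,
whole-aggregate drift with small per-cell jitter, and scheduled
divisions that replace a mother by two displaced daughters of half the
volume. Nucleus centres are sampled with a 2.5-diameter-fraction
minimum separation and each nucleus is shrunk, if necessary, to stay
0.4 µm clear of its Voronoi walls — nuclei are therefore disjoint and
strictly inside their cells by construction, and the ground-truth
meshes are exact analytic surfaces of the noiseless geometry.

It does **not** emulate realistic light-sheet optics, photobleaching,
dye-accumulation artifacts, mitotic envelope breakdown, or
non-star-convex cell shapes. Passing tests therefore demonstrate the
correctness and stability of the geometry/seeding/deformation/tracking
machinery under the stated imaging model, not segmentation accuracy on
real microscopy data.

## Label predictors

The oracle predictor returns the exact labels of the ground-truth
meshes, optionally corrupting the distance transform with seeded
Gaussian noise to emulate an imperfect network. The miniature 3D U-Net
(one encoder level, bottleneck, one decoder level with skip, three
heads: sigmoid mask/border and linear distance transform clipped to
[0, 32]) is implemented in pure numpy with hand-written gradients —
verified against finite differences in the test suite — and trained
with full-volume SGD on the composite loss. It is a testing vehicle for
the predictor contract, small enough to train on a phantom in seconds
on one CPU; it is not a production segmentation network. Anisotropic
stacks (e.g. 0.244 µm in-plane, 2 µm slice spacing) are made isotropic
by linear interpolation along z before any of this.

## Problem sizes

Tests and the acceptance script use: ≤ 64³ random blobs for the label
oracle; 64³ single-object phantoms for deformation recovery; a 128³
noiseless 10-cell aggregate for end-to-end closure; a 96³ 5-cell
aggregate over 6 frames for tracking; and a 96³ 5-cell aggregate run
twice for bitwise reproducibility. These sizes exercise every stage at
the phantom's native resolution while keeping a full run in the
minutes range on a single CPU.
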