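# Methods

This note records the models, algorithms, numerical conventions and design
choices behind `spinemorph`, and what its synthetic benchmarks do and do
not demonstrate about real data.

## Coordinate and data conventions

Voxel arrays are indexed `(z, y, x)` with spacing `(dz, dy, dx)` in
micrometres; a voxel centre sits at `index × spacing`, and every mesh lives
in that physical frame. The default spacing `(0.1, 0.025, 0.025) µm`
matches high-resolution confocal acquisition (0.1 µm z-steps, 0.025 µm
lateral pixels), giving 4× worse axial than lateral sampling — the central
resolution asymmetry the whole pipeline must live with.

## Binarization

The threshold at voxel `v` blends a user-set global level with the local
window mean: `Thres(v) = base_thres·(1−t) + t·LocalThres(v)`, `t ∈ [0,1]`.
The local mean window defaults to 5×15×15 voxels (z, y, x) — roughly a
spine diameter in each direction at the default spacing; near borders the
mean is taken over in-bounds voxels only (no padding). Foreground requires
the intensity to *strictly* exceed the threshold, which makes the fully
adaptive limit on a uniform image well defined (empty mask); box sums are
computed via prefix sums so a uniform image's local mean is bit-identical
to its value and the strict rule stays sharp. Raising `base_thres` can only
remove foreground (monotonicity), which the tests verify against a literal
per-voxel evaluation of the formula. Under the single-dendrite assumption,
everything but the largest connected foreground component is discarded as
shot noise before surface extraction.

## Surface reconstruction

Surface samples are the foreground voxels removed by one 6-connected
erosion; normals are the negated gradient of a Gaussian-smoothed
(σ = 1 voxel) copy of the mask — the raw binary gradient is ±1-quantized
and too coarse to orient a surface. Because the continuum boundary lies
midway between the last foreground and first background voxel centres,
each sample is pushed half a voxel outward along its normal; without this
offset reconstructed objects are biased small by half a voxel per side
(≈ 7% of the volume of a 2 µm sphere at 0.05 µm voxels).

The mesh itself comes from an oriented-point implicit: the signed distance
at a grid point is the projection of its offset from the nearest sample
onto that sample's normal, lightly smoothed (σ = 0.5 cells), and the zero
level set is extracted with marching cubes on a grid padded three cells
beyond the samples so the surface always closes. The contract downstream
is purely geometric — any watertight, outward-oriented mesh enclosing the
samples would do. Robustness ladder: if the level set does not close, the
field is re-smoothed (+1, then +2 cells) before failing; connected
components below 1% of the total area, and components that cannot be
closed by hole filling, are dropped. A digitized 2 µm ball at 0.05 µm
voxels reconstructs to within ~3% of its analytic volume.

## Skeletonization and shaft identification

The skeleton backend voxelizes the mesh interior (default pitch: longest
bbox extent / 100), thins it with 3D morphological skeletonization, links
skeleton voxels by 26-connectivity, keeps the largest component, and maps
every mesh vertex to its nearest skeleton node. Voxel thinning leaves
lattice-scale zigzag, so interior (degree-2) node positions are relaxed
toward their neighbour means (15 iterations, λ = 0.5) — without this the
turning-angle sums below are dominated by noise that grows with path
length.

Cycles (thinning can close small loops) are broken by removing one edge in
the longest chain of each cycle, keeping every node. Degree-2 chains are
collapsed into annotated edges of a reduced graph whose nodes are leaves
and junctions only. All leaf-to-leaf paths are ranked by expanded node
count; among the five longest, the path minimizing the sum of unsigned
turning angles **over its reduced (anchor) node sequence** is the shaft —
junction-to-junction legs are straight by construction, so this comparison
measures genuine bends (a turn into a spine) rather than voxel wiggle.
Two corrections handle thinning pathology near the volume ends, where the
skeleton retracts by up to a couple of micrometres:

* a terminal leg of the chosen path that turns more than 60° away from the
  path direction (windowed directions over the outer 35% of the path) is
  trimmed — it is a spine captured as the path terminus;
* the shaft polyline is extrapolated beyond each endpoint along a
  principal-axis fit of the terminal node run (the last few, wandering
  nodes excluded from the fit), so vertices near the cut faces are
  measured against the axis rather than the retracted tip.

## Spine/shaft labeling and extraction

Vertices mapped to skeleton nodes outside the shaft are labeled spine;
vertices mapped to shaft(-like) nodes receive their distance to the
nearest point of the shaft polyline (segments, not nodes, so node spacing
does not quantize anything), and those strictly above the
`SENSITIVITY`-quantile of that distance distribution (linear-interpolation
quantile) are relabeled spine. Branch nodes lying within 1.3× the median
shaft-vertex distance of the polyline are treated as shaft-like: spine
branches begin at the shaft axis, and surface vertices all around the
junction — including the far side of the shaft — contract onto them.
Two rounds of majority-vote label smoothing over mesh neighbourhoods
remove speckle labels and thin gaps that would shatter one spine into
fragments.

Spine-labeled connected components keep only faces whose three vertices
belong to the component; each boundary loop (split into simple loops if a
walk revisits a vertex) is closed by a triangle fan from its centroid. The
base centroid `c` is the area-weighted centroid of the largest patch.
Components with fewer than `min_vertices` vertices (default 20) or less
than `min_volume` enclosed volume are discarded: a near-flat sliver of
mislabeled shaft surface has almost no volume, while any resolvable spine
encloses a physical amount of it. The pipeline wrapper additionally drops
spines touching the field-of-view border along the dendrite axis —
structures cut by the crop cannot be measured.

## Morphometric features

All distance-based features use the true surface vertices (fan apexes
excluded, boundary-loop vertices included — they lie on the real surface)
measured from `c`. `L` averages the top `max(1, ⌈0.05·N⌉)` distances;
`CVD` uses the population standard deviation (it describes, it does not
estimate); `OA` averages the unsigned angle between each direction
`p_i − c` and the mean direction, and is recorded as NaN with a warning
when the mean direction vanishes (radially symmetric spine). Volume uses
the divergence theorem (absolute value, warning if the mesh is inward-
oriented); the convex hull is qhull's. `L`/`AD` scale linearly, `S`/`FA`
quadratically, `V`/`CHV` cubically; `CHR`/`CVD`/`OA` are scale-free, and
everything is rigid-motion invariant — all property-tested.

## CLDH

Chords are sampled by drawing two area-uniform surface points (triangle
area-weighted, uniform barycentric), casting a ray from one bounding-box
diagonal before the first point through both, batch-intersecting it with
every triangle (vectorized Möller–Trumbore, float64), sorting and
deduplicating hits (tolerance 1e-9 × bbox diagonal), and pairing them
consecutively into interior segments. Rays with odd intersection counts
are discarded and counted; a discard fraction above 50% aborts as a broken
mesh. Lengths are divided by the per-object maximum (stored so absolute
scale is recoverable) and binned into 100 equal bins on [0, 1]. 30,000
chords is the default: replicate histograms of the same spine are no
longer distinguishable there (their JSD plateaus), which the convergence
helper exposes. The Jensen–Shannon distance uses base-2 logarithms so
values lie in [0, 1]; `0·log 0 ≡ 0`.

## Classification

Consensus = modal expert label, ties → outlier. Training data drops
outlier and filopodia spines, undersamples every class to the minority
count (seeded), and z-scores classic columns (CLDH rows are already
probabilities). Multiclass SVMs are one-vs-one with `C = 1`; RBF
`σ` defaults to the median pairwise Euclidean distance and Laplacian `γ`
to the reciprocal median L1 distance; histogram-intersection and Laplacian
kernels enter the solver as precomputed Gram matrices (all four are
verified symmetric PSD). Accuracy sweeps use stratified splits that
preserve class shares at each training ratio, averaged over trials.

## Clustering

k-means is best-of-10 restarts; DBSCAN supports Euclidean or (for CLDH
rows) the package's own Jensen–Shannon distance via a precomputed matrix,
with `min_neighbors = 4`, consistent with the 3-NN `φ(ε)` curve used for
its elbow. The WSS elbow is the interior grid point of maximum turning
angle of the min-max-normalized curve (ties toward smaller k; a straight
curve warns and returns the smallest interior point). The silhouette is
the standard per-sample Rousseeuw form, averaged, noise excluded. The
max-class-divergence score normalizes the mean pairwise Euclidean row
distance of the cluster-by-class matrix by √2 so it spans [0, 1]; a JSD
row metric is available as an option. The default k grid is 2–15, and an
optional PCA pre-reduction (95% variance) is provided for classic-space
clustering.

## Synthetic data: what it emulates, and what it does not

Archetypes are solids of revolution: hemisphere (stubby), capsule
(filopodia), neck cylinder + spherical head (thin/mushroom; head centre at
`ln + sqrt(rh² − rn²)` so the sphere meets the neck tangentially). Rings
are uniform in profile arc length with a fixed azimuthal count (48), the
base ring is fan-patched to the origin (the patch doubles as ground-truth
`FA`), and volume/lateral area have closed forms. Parameter ranges follow
the qualitative class descriptions (e.g. mushroom heads 0.3–0.5 µm on
0.08–0.12 µm necks) since no numeric priors exist; optional radial jitter
is bounded by 2% of the head radius.

Scenes are analytic unions (shaft capsule + posed spines) cropped like a
real image — the shaft overhangs the crop so the stack contains a shaft
running through its x borders, not a capped rod. Occupancy, surface
ownership and per-spine truth volumes (spine solid minus shaft, midpoint
quadrature at 0.02 µm) come from the solids; the scene mesh is marching
cubes on the union SDF (grid offset by an irrational pitch fraction so no
lattice plane coincides with a crop plane). Rasterization sets inside
voxels to intensity 100, blurs with an anisotropic Gaussian PSF
(σ = 0.10 µm axial, 0.05 µm lateral — resolvable-but-realistic; no Airy or
Richardson–Lucy modeling), adds Gaussian noise (SD 10) and clips at zero.
Spines protrude mostly laterally, as in analyses that favour spines
resolvable in the imaging plane.

The volumetric recovery benchmark uses an all-mushroom population with
sturdy necks (head 0.35–0.5 µm, neck 0.13–0.16 µm, length 0.45–0.7 µm,
five spines on a 14 µm shaft, ≥ 2.5 µm from the crop ends) and analysis
parameters `base_thres = 40` (below half-maximum, offsetting PSF erosion
of curved surfaces), blend 0.3, sensitivity 0.9, skeleton pitch 0.08 µm,
`min_vertices = 300`, `min_volume = 0.05 µm³`. Volumetric ground truth is
only well-posed for clearly protruding spines: stubby spines barely exceed
the distance-quantile rule and the location of their cut is ambiguous at
this resolution (interactive curation, which the original workflow uses
for such cases, is out of scope here — the `sensitivity`, `min_vertices`
and `min_volume` knobs are its automated stand-ins). Mixed populations
remain the default for labeling-accuracy and counting tests.

Passing these benchmarks shows the pipeline is internally consistent and
recovers known geometry under realistic sampling, blur and noise. It does
not certify performance on real tissue, where uneven labeling, photon
noise, curved shafts, touching spines and imaging artifacts all occur and
none are modeled.

## Known limitations

* The skeleton backend is a voxel thinning, not a mean-curvature-flow
  skeleton; its end-retraction corrections are heuristics with tunable
  angles (60°) and margins (1.3× median radius) chosen once and kept.
* A single global distance quantile cannot adapt to shafts of varying
  radius; strongly tapering dendrites would need a local rule.
* One dendrite per stack is assumed throughout shaft selection.
* The CLDH is surjective: distinct shapes can share a histogram.
* DBSCAN is provided for completeness but, as with the density structure
  of real spine data, tends to produce many small clusters plus noise;
  the k-means criteria are the recommended route.
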