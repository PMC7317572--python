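# Methods

This note documents the models, estimators and numerical choices behind
`panicle3d`, in the order the pipeline runs them, together with what the
synthetic phantoms do and do not establish about real scans.

## Intensity standardization

CT reconstructions arrive on arbitrary scanner-dependent intensity
scales. Every volume is mapped affinely so that the air (background)
mode lands at 0 and a reference anchor at 1000. The air mode is the
largest histogram peak below the overall median (air dominates the
field of view); the anchor is the modal intensity of a reference-marker
region when one was scanned alongside the sample, and otherwise the
99.5th intensity percentile. The anchor constants 0/1000 are arbitrary
but fixed: every downstream threshold (panicle 300, seed 750) is
expressed on this scale. The map is monotone, idempotent, and invariant
under affine transforms of the raw data; both properties are tested.
The histogram uses 512 bins spanning the data range (affine-equivariant
by construction) and refines the modal bin to its median value.

Cropping keeps everything from about 1 cm below the lowermost rachis
node upward (`round(10 mm / voxel_edge)` slices) plus a 2-voxel x/y
margin around the foreground.

## Panicle shape

The panicle mask is the largest 26-connected component above the
panicle threshold. Conventions that matter:

* **Convex hulls** are computed over voxel *cubes* (centers ± ½ voxel),
  so a digitally solid convex body has solidity exactly 1; hulls over
  bare centers would make solidity overshoot 1 by one boundary layer.
* **Elongation/flatness** are √(λ₂/λ₁) and √(λ₃/λ₂) of the
  voxel-coordinate covariance — monotone ratios in (0, 1], 1 =
  isotropic. Under this sign convention flat, wide panicles score a
  *low* flatness. Whether the underlying study used square-rooted or
  raw eigenvalue ratios is not recoverable; the two are monotone
  equivalents, which is all the rank-based statistics consume.
* **MaxWidth** is the largest per-slice horizontal Feret (caliper)
  diameter, rotation-invariant in the horizontal plane, plus one voxel
  for the two half-voxel boundary layers.
* The **side-view projection** collapses the horizontal axis of least
  voxel-coordinate variance, showing the widest face; a pixel is set
  iff any voxel lies along its ray. 2D analogs (area, moment-ellipse
  axes, hull area, perimeter, circularity 4πA/P²) come from
  scikit-image region properties plus the same corner-hull rule.

## Seed segmentation

Order of operations: threshold → noise filter → split → shape filter.

1. 26-connected components above the seed threshold.
2. Pieces smaller than ⅛ of the mean component volume (mean taken once
   over all inputs) are noise.
3. Components holding several touching seeds are split by morphological
   opening: erosion by a ball (default radius 2 voxels ≈ 430 µm at the
   default phantom scale), labeling of the surviving cores, and
   reassignment of every original voxel to its nearest core (Euclidean,
   via the distance transform's index map). Nearest-core assignment —
   rather than plain re-dilation — makes the output an exact partition
   of the component; for the convex-ish unions produced by touching
   seeds it coincides with the geodesic variant. A component whose
   erosion leaves ≤ 1 core is returned unchanged.
4. Pieces whose covariance axis ratio a/c exceeds 4 (eigenvalues
   floored at 1/12 voxel², the variance of a single voxel) are shape
   outliers — typically long branch fragments above the threshold.

Morphology is measured on up to 100 seeds: 10 equal-height rachis bins
× 10 seeds drawn (seeded RNG, without replacement) from those above the
bin's 25th volume percentile, which avoids underdeveloped seeds. The
percentile uses linear interpolation (type 7) with strict `>`
candidacy; at small n this choice decides borderline candidates, so it
is fixed and documented here.

### Ellipsoid fit and radius histogram

The moment fit takes the centroid, covariance eigenvectors, and
semi-axes √(5λᵢ) — exact for a uniform solid ellipsoid; voxelization
adds ~1/12 voxel² per eigenvalue, under 2% for phantom-scale seeds. The
fit error is the mean over surface voxels of |‖v − c‖ − r_ellipsoid(v̂)|.
Its floor is set by half-voxel surface quantization (≈ 0.5 voxel for a
10×6×4-voxel ellipsoid); it is a relative shape-regularity measure, not
an absolute accuracy claim.

The radius histogram samples ~1000 Fibonacci-lattice directions. Each
direction's radius is the farthest surface voxel within a small angular
cone (1.5 lattice spacings) — surface voxels can be sparser than
directions, and the cone maximum keeps every direction supported
instead of silently under-reporting. Radii are normalized by their mean
and binned into 10 bins on [0.5, 1.5], outliers clipped into the end
bins. Tests pin scale invariance and rotation invariance to 0.05 per
bin. The per-panicle histogram is the renormalized mean of per-seed
histograms (mean-of-histograms, not pooled rays — the alternative
pooling is not distinguishable from the published description and is
noted in the configuration).

## Seed spatial traits

Ten equal-height bins over the panicle mask's z-extent (mask extent,
not seed extent, so bins are comparable across trait families), ordered
apex → base. Number and biomass histograms are normalized to fractions
for cross-panicle comparability (raw counts are also emitted); the size
histogram stays in mm³ because it is a per-bin mean. Seed–rachis
distances are point-to-polyline distances (segment-wise projection,
never vertex-only) from seed centroids to the stem polyline.

## Skeleton and branch architecture

The cited medial-axis algorithms of the original workflow are replaced
by a contract-equivalent chain: homotopy-preserving 3D thinning
(scikit-image's Lee-style skeletonization) of the downsampled,
thresholded, hole-filled seedless volume, with the Euclidean distance
transform supplying a per-vertex radius, and iterative pruning of twigs
shorter than 1.5× the radius at their supporting junction. The
downstream logic needs only the stated contract — 1D, connected,
homotopy-preserving, noise-pruned, radius-equipped — which tests verify
directly (cylinder axis and radius, Y-junction count, loop preservation
on a solid torus). Practical hardening: hole filling runs both in 3D
and per-slice (a hollow stem cut open at the ends is not an enclosed
cavity); thinning is retried under axis permutations/reflections
because the sweep order can annihilate grid-symmetric shapes; and the
longest edge of every 26-adjacency triangle is dropped so junctions are
single vertices rather than small cliques.

**Stem.** Hysteresis on the vertex radii: a core at the 85th radius
percentile is grown through vertices above a permissive threshold — the
60th percentile capped at 0.6× the core threshold, with automatic
backoff (0.45×, 0.3×, minimum) if the region still comes apart; the
cap is needed because a percentile alone can exceed the stalk's own
radius variation when thin branches dominate the vertex count. The stem
is the bottleneck-widest path (maximum spanning tree on min-radius edge
weights) between the lowest and highest *core* vertices — anchoring on
the core matters because branch tips can overtop a tapering stalk apex
— then extended toward both stalk ends along the widest continuations
whose (neighborhood-maximum) radius stays above half the stem median.
The polyline is smoothed by a ±4-vertex moving average: raw voxel paths
zigzag, inflating arc lengths by several percent and corrupting local
tangents. Reported stem length adds one local radius per end to undo
thinning's end retraction. `MainStalkDiameter` is twice the median
vertex radius along the stem.

**Nodes and branches.** Every stem vertex with an off-stem neighbor
seeds a traversal that picks, at each junction, the continuation with
the smallest turning angle, stopping at a leaf; paths shorter than
5 mm are rejected, and nodes closer than 2 mm of stem arc are merged
(whorls). Two voxel-scale biases are corrected by line fits over the
branch's *clean region* — vertices outside 1.3× the stem radius and
short of the final 1.5 tube radii, fitted by total least squares with
one outlier-trimmed refit (seed scars dent the tube):

* the **node position** is the closest approach between that line and
  a local stem line fitted away from the junction (the stem polyline
  itself bulges toward the branch there); this removes the
  junction-displacement bias of thinning near a thick stalk;
* the **tip angle** is the angle between that line's direction and the
  upward stem tangent (window of ±4 stalk radii of arc, length
  preserved at the stem ends). At the working resolution a literal
  distal-10% window spans 3–5 voxels and is quantization-dominated
  (±7° on phantoms); the clean-region fit recovers phantom angles to
  ~1° and equals the distal tangent exactly for straight branches.
  `PrimaryBranchTipAngle` is the mean over branches (per-branch values
  are exported).

`FirstPrimaryBranchLength` uses the lowest-node convention. Internodes
are arc distances between consecutive merged nodes; with fewer than two
nodes the internode traits are absent rather than zero.

## Statistics

* Replicates are averaged per accession before any test.
* Kruskal–Wallis p-values are BH-adjusted jointly across the 37
  stand-alone traits; the pairwise Mann–Whitney family is BH-adjusted
  jointly across all trait × race-pair combinations (the alternative —
  within-trait adjustment — is noted as ambiguous in the source
  description; the joint family is the stricter reading). Mann–Whitney
  uses the asymptotic method with tie correction for determinism.
  Compact letter displays use insert-and-absorb over groups ordered by
  decreasing mean.
* Variance: Bartlett omnibus, pairwise Brown–Forsythe = Levene with
  median centering.
* The distributional permutation test reports p = #{Xᵢ > X₀}/n_perm
  with strict inequality, so it can return exactly 0; a +1-corrected
  estimator is available but off by default to match the printed
  definition. Tests compare it against exhaustive enumeration of all
  20 splits of 3+3 groups.
* PCA z-scores every trait (constant columns dropped with a warning)
  and decomposes the correlation matrix; variance explained sums
  to 100%.
* PCA–LDA LOOCV fits the PCA once on the full table and cross-validates
  the LDA on the fixed 8-PC scores; refitting scaler+PCA inside each
  fold is available behind `refit_pca=True`. The fixed-scores default
  follows the reading that the same eight PC scores feed every fold.
* The Mantel test (Pearson over strictly-lower triangles, simultaneous
  row/column permutation, one-sided greater, +1 correction) is
  implemented in-package so its RNG is seedable; scikit-bio's
  implementation serves as an independent oracle in the tests. Kinship
  (a similarity) is negated by the caller to act as a distance.
* k-means uses 25 restarts per k with a seeded RNG; the clustergram
  row-standardizes the 77×5 race-mean matrix and clusters both ways
  with average-linkage Euclidean.

## Synthetic phantoms

Phantoms render a vertically tapered stalk (base radius 2.5 mm, tip
1.2 mm), straight branch tubes (radius 0.7 mm) at configured node
arcs/angles/lengths with golden-angle azimuth spread, and jittered
ellipsoidal seeds (default semi-axes 1.4 × 1.0 × 0.8 mm) attached along
the branches, overlapping the tube by only ~0.2 of their minor
semi-axis so digital seed removal leaves the branch nearly intact.
Intensities follow the standardized scale (air 0, tissue 600, seeds
900) with additive Gaussian noise (default SD 30). Touching pairs (10%
by default) share ≲10% volume along the major axis. Placement enforces
a ≥2-voxel surface gap between non-touching seeds — using directional
ellipsoid radii — so ground-truth seed counts are recoverable by
construction; the label map records every voxel's provenance.

The default voxel edge is 214 µm — the working resolution of a
~107 µm scan after the 2× downsampling the skeleton stage performs —
with a 60 mm panicle, keeping default grids well under 512³ and a full
extraction around 3 s. The acceptance suite uses 20 noiseless
open-architecture phantoms (heights 36–48 mm, 5–7 nodes, insertion
angles 35–50°, grids ≈ 300×150×150) chosen so the whole recovery run
fits comfortably on one CPU; measured recovery there is: seed and
branch counts exact, internode error ≤ 2 working-resolution voxels
(mean ≈ 0.3 mm), tip angles within 3° (mean < 1°), ellipsoid semi-axes
within 5% (mean < 1%).

**What phantoms do not show.** They contain no beam hardening, ring
artifacts, partial-volume blur, glumes/awns, curved or drooping
branches, branch–branch intersections, or seeds compressed against
each other in dense heads. Passing the recovery suite therefore
demonstrates correctness of the geometry and statistics, not field
robustness on compact panicles — the branch tracer is expected to
degrade where branches intersect, which is why compact-architecture
recovery is only held to approximate count agreement.

## Degenerate inputs and numerical conventions

Flat-histogram volumes raise a standardization error; empty foreground
raises a segmentation error, except seed segmentation, which warns and
returns zero seeds (a seedless panicle is a valid sample). Coplanar
voxel sets raise a hull error; seeds under 20 voxels are not fitted.
Ties in the bottleneck path are broken toward larger total radius. All
RNG-dependent steps (seed sampling, permutations, k-means, phantom
rendering) accept explicit seeds and are bit-reproducible under them.
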