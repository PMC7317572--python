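# panicle3d

3D X-ray computed-tomography phenotyping of cereal inflorescences.
From a voxel volume of a *Sorghum bicolor* panicle, `panicle3d` segments
the whole panicle and every seed (caryopsis), digitally removes the
seeds, skeletonizes the remaining branch architecture, and emits a
77-trait record — 37 stand-alone scalars and 40 distributional traits
(four 10-bin histograms) — in five categories:

| category | traits | examples |
|---|---|---|
| 3D panicle | 8 | `PanicleVolume`, `PanicleSolidity`, `PanicleElongation` |
| 2D panicle (side-view projection) | 9 | `Panicle2DArea`, `Panicle2DCircularity` |
| seed morphology | 19 | `SeedNumber`, `SeedAvgVolume`, `SeedshapeRhist1..10` |
| seed spatial | 33 | `AvgDistanceSeedMainStalk`, `SeedNumbervhist1..10` |
| branch architecture | 8 | `PrimaryBranchNumber`, `LongestInternodeLength`, `MainStalkDiameter` |

It also implements the statistics used to compare such trait tables
across the five botanical races of sorghum (Bicolor, Caudatum, Durra,
Guinea, Kafir): Kruskal–Wallis and pairwise Mann–Whitney *U* tests with
joint Benjamini–Hochberg adjustment, Bartlett and Brown–Forsythe
variance tests, a 1000-permutation L2 test for 10-bin distributional
traits, PCA, PCA–LDA with leave-one-out cross-validation, Mantel tests
against a kinship matrix, two-way hierarchical clustering of race
means, and k-means with silhouettes.

A synthetic phantom generator renders panicles with exhaustive ground
truth (tapered stalk, branches at configured node heights/angles,
ellipsoidal seeds, optional touching pairs and Gaussian noise), so the
whole pipeline is testable without scans.

## The core measurements

**Seed shape.** Each seed is quantified by a moment-matched ellipsoid
(semi-axes a ≥ b ≥ c from the covariance eigenvalues λᵢ via √(5λᵢ)),
elongation and flatness both as covariance ratios (√(λ₂/λ₁), √(λ₃/λ₂))
and as axis ratios (b/a, c/b), the mean radial deviation from the
fitted ellipsoid (`SeedEllipsoidError`), and a scale- and
rotation-invariant histogram of the directional radius r(d̂) over ~1000
uniformly distributed directions, normalized by its mean and binned on
[0.5, 1.5] (`SeedshapeRhist1–10`).

**Branch architecture.** The seedless panicle is downsampled 2×,
thresholded, hole-filled, and thinned to a curve skeleton whose
vertices carry the Euclidean-distance-transform radius. The rachis is
the bottleneck-widest path (maximizing the minimum radius) through a
hysteresis-selected thick region; junctions along it are nodes, and
branches are traced outward choosing the straightest continuation at
every junction. Internodes are arc distances between consecutive
(merged) nodes; the tip angle is the angle between the distal branch
tangent and the upward rachis direction.

**Race statistics.** For a 10-bin distributional trait, two races A, B
are compared by X₀ = ‖mean_A − mean_B‖₂ against the permutation null
Xᵢ from reshuffled race labels, with p = #{Xᵢ > X₀}/n_perm.

## Worked example

```python
from panicle3d import PhantomSpec, generate_phantom, extract_all_features

vol, truth = generate_phantom(PhantomSpec(rng_seed=1))  # 60 mm panicle, 8 branches
record = extract_all_features(vol)
print(record[["PanicleDepth", "SeedNumber", "PrimaryBranchNumber",
              "PrimaryBranchTipAngle", "LongestInternodeLength",
              "MainStalkDiameter"]])
```

prints (values in mm, counts, degrees):

```
PanicleDepth              69.122
SeedNumber                59.000
PrimaryBranchNumber        8.000
PrimaryBranchTipAngle     39.709
LongestInternodeLength     6.216
MainStalkDiameter          3.424
```

The phantom was rendered with 8 branches at 40° carrying 66 seeds, with
scan-like noise and a 10% chance of touching seed pairs. Branch count
and tip angle are recovered nearly exactly; 59 of 66 seeds are found
because some touching pairs survive the morphological-opening split —
on noiseless phantoms with separated seeds the count is exact.
`PanicleDepth` exceeds the 60 mm stalk because the topmost branches
overtop the stalk apex.

The same pipeline runs from the shell:

```bash
panicle3d phantom --seed 1 --out vol.nrrd --truth truth.json
panicle3d extract --input vol.nrrd --out traits.json
panicle3d stats --traits table.csv --labels races.csv --out report/
```

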