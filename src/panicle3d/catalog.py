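"""The 77-trait catalog: names and category structure.

Traits come in five categories (3D panicle, 2D panicle, seed morphology,
seed spatial, branch architecture) holding 8/9/19/33/8 traits; 37 are
stand-alone scalars and 40 are distributional (four 10-bin histograms).
Column names here are the canonical header of every trait table the
package reads or writes.
"""

from __future__ import annotations


def _hist(prefix: str) -> list[str]:
    return [f"{prefix}{i}" for i in range(1, 11)]


PANICLE_3D_FEATURES = [
    "PanicleVolume",
    "PanicleDepth",
    "PanicleMaxWidth",
    "PanicleWidthDepthRatio",
    "PanicleConvexHullVolume",
    "PanicleSolidity",
    "PanicleElongation",
    "PanicleFlatness",
]

PANICLE_2D_FEATURES = [
    "Panicle2DArea",
    "Panicle2DMajorAxisLength",
    "Panicle2DMinorAxisLength",
    "Panicle2DAspectRatio",
    "Panicle2DConvexHullArea",
    "Panicle2DSolidity",
    "Panicle2DPerimeter",
    "Panicle2DDepth",
    "Panicle2DCircularity",
]

SEED_MORPHOLOGY_STANDALONE = [
    "SeedNumber",
    "SeedNumberPerDepth",
    "SeedTotalVolume",
    "SeedAvgVolume",
    "SeedElongation_cov",
    "SeedFlatness_cov",
    "SeedElongation_ell",
    "SeedFlatness_ell",
    "SeedEllipsoidError",
]
SEED_MORPHOLOGY_FEATURES = SEED_MORPHOLOGY_STANDALONE + _hist("SeedshapeRhist")

SEED_SPATIAL_STANDALONE = [
    "MinDistanceSeedMainStalk",
    "AvgDistanceSeedMainStalk",
    "MaxDistanceSeedMainStalk",
]
SEED_SPATIAL_FEATURES = (
    SEED_SPATIAL_STANDALONE
    + _hist("SeedNumbervhist")
    + _hist("SeedBiomassvhist")
    + _hist("SeedSizevhist")
)

BRANCH_FEATURES = [
    "PrimaryBranchNumber",
    "PrimaryBranchNumberPerDepth",
    "FirstPrimaryBranchLength",
    "PrimaryBranchAvgLength",
    "LongestInternodeLength",
    "SecondLongestInternodeLength",
    "PrimaryBranchTipAngle",
    "MainStalkDiameter",
]

FEATURE_CATEGORIES: dict[str, list[str]] = {
    "panicle_3d": PANICLE_3D_FEATURES,
    "panicle_2d": PANICLE_2D_FEATURES,
    "seed_morphology": SEED_MORPHOLOGY_FEATURES,
    "seed_spatial": SEED_SPATIAL_FEATURES,
    "branch": BRANCH_FEATURES,
}

ALL_FEATURES: list[str] = [f for feats in FEATURE_CATEGORIES.values() for f in feats]

DISTRIBUTIONAL_FEATURES: list[str] = (
    _hist("SeedshapeRhist")
    + _hist("SeedNumbervhist")
    + _hist("SeedBiomassvhist")
    + _hist("SeedSizevhist")
)

STANDALONE_FEATURES: list[str] = [f for f in ALL_FEATURES if f not in DISTRIBUTIONAL_FEATURES]

HISTOGRAM_GROUPS: dict[str, list[str]] = {
    "SeedshapeRhist": _hist("SeedshapeRhist"),
    "SeedNumbervhist": _hist("SeedNumbervhist"),
    "SeedBiomassvhist": _hist("SeedBiomassvhist"),
    "SeedSizevhist": _hist("SeedSizevhist"),
}

RACES = ["Bicolor", "Caudatum", "Durra", "Guinea", "Kafir"]
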