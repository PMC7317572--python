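"""End-to-end trait extraction: one standardized volume → 77 traits.

Stages run in the order the pipeline is built around: panicle
segmentation and 3D/2D shape traits; seed instance segmentation and
morphology; digital seed removal and skeletonization of the seedless
panicle; stem/node/branch identification; and finally the seed spatial
traits, which need both the seeds and the rachis polyline.  A failing
stage logs a warning, marks its traits (and its dependents') as absent,
and the run continues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import panicle, seeds as seeds_mod, skeleton as skel_mod, spatial
from .catalog import ALL_FEATURES
from .volume import VoxelVolume


@dataclass
class PipelineConfig:
    """Tunable parameters of the extraction pipeline (standardized-intensity
    thresholds, morphology radii in voxels, skeleton lengths in mm)."""

    panicle_threshold: float = panicle.PANICLE_THRESHOLD
    seed_threshold: float = seeds_mod.SEED_THRESHOLD
    opening_radius: int = seeds_mod.DEFAULT_OPENING_RADIUS
    max_axis_ratio: float = seeds_mod.DEFAULT_MAX_AXIS_RATIO
    n_directions: int = 1000
    skeleton_downsample: int = 2
    prune_factor: float = 1.5
    stem_high_percentile: float = 85.0
    stem_low_percentile: float = 60.0
    min_branch_len: float = 5.0
    node_merge_dist: float = 2.0
    rng_seed: int = 0


def extract_all_features(
    vol: VoxelVolume,
    config: PipelineConfig | None = None,
    return_details: bool = False,
):
    """Run every stage on a standardized volume and emit the 77-trait record.

    Returns a :class:`pandas.Series` indexed by the canonical trait
    names (NaN where a stage failed); with ``return_details=True`` also
    returns a dict of stage intermediates (masks, seed instances,
    skeleton, stem, branches).
    """
    cfg = config or PipelineConfig()
    record: dict[str, float] = {f: np.nan for f in ALL_FEATURES}
    details: dict[str, object] = {}
    rng = np.random.default_rng(cfg.rng_seed)

    pmask = None
    depth = np.nan
    z_range = None
    try:
        pmask = panicle.segment_panicle(vol, cfg.panicle_threshold)
        record.update(panicle.panicle_3d_features(pmask))
        depth = record["PanicleDepth"]
        zs = np.nonzero(pmask.mask.any(axis=(1, 2)))[0]
        z_range = (zs.min() * pmask.voxel_mm, (zs.max() + 1) * pmask.voxel_mm)
        details["panicle_mask"] = pmask
        img, pixel_mm = panicle.project_side_view(pmask)
        record.update(panicle.panicle_2d_features(img, pixel_mm))
        details["projection"] = img
    except Exception as exc:  # noqa: BLE001 - stage isolation
        warnings.warn(f"panicle stage failed: {exc}", stacklevel=2)

    seed_labels = None
    seed_list: list[seeds_mod.SeedInstance] = []
    try:
        seed_labels, seed_list = seeds_mod.segment_seeds(
            vol, cfg.seed_threshold, cfg.opening_radius, cfg.max_axis_ratio)
        details["seed_labels"] = seed_labels
        details["seeds"] = seed_list
        if seed_list and z_range is not None:
            sampled = seeds_mod.sample_seeds(seed_list, z_range, rng)
            details["sampled_seeds"] = sampled
            record.update(seeds_mod.seed_summary(seed_list, sampled, depth))
        elif not seed_list:
            record["SeedNumber"] = 0.0
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"seed stage failed: {exc}", stacklevel=2)

    stem = None
    try:
        seedless = skel_mod.remove_seeds(vol, seed_labels) if seed_labels is not None else vol
        mask, coarse_edge = skel_mod.prepare_mask(
            seedless, cfg.panicle_threshold, cfg.skeleton_downsample)
        skeleton = skel_mod.skeletonize_with_radius(mask, coarse_edge, cfg.prune_factor)
        details["skeleton"] = skeleton
        stem = skel_mod.identify_stem(
            skeleton, cfg.stem_high_percentile, cfg.stem_low_percentile)
        details["stem"] = stem
        branches = skel_mod.detect_nodes_and_branches(
            skeleton, stem, cfg.min_branch_len, cfg.node_merge_dist)
        details["branches"] = branches
        record.update(skel_mod.branch_traits(branches, stem, depth))
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"skeleton stage failed: {exc}", stacklevel=2)

    try:
        if seed_list and z_range is not None:
            dist = spatial.axial_distributions(seed_list, z_range)
            record.update({k: v for k, v in dist.items() if not k.startswith("_")})
            if stem is not None:
                record.update(spatial.seed_stalk_distances(seed_list, stem.polyline))
    except Exception as exc:  # noqa: BLE001
        warnings.warn(f"seed spatial stage failed: {exc}", stacklevel=2)

    series = pd.Series({f: record.get(f, np.nan) for f in ALL_FEATURES},
                       name=vol.name, dtype=float)
    if return_details:
        return series, details
    return series
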