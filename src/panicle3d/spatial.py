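"""Seed spatial traits: axial distributions and seed-to-rachis distances.

Distributions are discretized into 10 equal-height bins over the
panicle's z-extent, ordered apex → base (bin 1 is the top of the
panicle).  Number and biomass histograms are normalized to fractions so
panicles of different fertility are comparable; the size histogram
keeps raw mm³ (it is a per-bin *mean* seed volume, not a mass share).
"""

from __future__ import annotations

import numpy as np

from .seeds import SeedInstance


def axial_distributions(
    seeds: list[SeedInstance],
    panicle_z_range: tuple[float, float],
    n_bins: int = 10,
) -> dict[str, float]:
    """Per-bin seed count (fraction), summed volume (fraction) and mean
    volume (mm³) along the rachis, apex → base."""
    z_lo, z_hi = panicle_z_range
    edges = np.linspace(z_lo, z_hi, n_bins + 1)
    zs = np.array([s.centroid_mm[0] for s in seeds])
    vols = np.array([s.volume_mm3 for s in seeds])
    # np.digitize with right-open bins; clamp top edge into last bin
    bin_idx = np.clip(np.digitize(zs, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(bin_idx, minlength=n_bins).astype(float)
    biomass = np.bincount(bin_idx, weights=vols, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        size = np.where(counts > 0, biomass / np.where(counts > 0, counts, 1), 0.0)
    # bins are indexed bottom→top in z; apex (top) first
    counts, biomass, size = counts[::-1], biomass[::-1], size[::-1]
    out: dict[str, float] = {}
    num_frac = counts / counts.sum() if counts.sum() > 0 else counts
    bio_frac = biomass / biomass.sum() if biomass.sum() > 0 else biomass
    for i in range(n_bins):
        out[f"SeedNumbervhist{i + 1}"] = float(num_frac[i])
        out[f"SeedBiomassvhist{i + 1}"] = float(bio_frac[i])
        out[f"SeedSizevhist{i + 1}"] = float(size[i])
    # raw values also emitted for downstream use
    out["_raw_counts"] = counts
    out["_raw_biomass"] = biomass
    return out


def point_to_polyline_distance(points: np.ndarray, polyline: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest point on a polyline (segment-wise)."""
    points = np.atleast_2d(points)
    if polyline.shape[0] == 1:
        return np.linalg.norm(points - polyline[0], axis=1)
    p0 = polyline[:-1]
    d = polyline[1:] - p0  # (m, 3)
    len2 = (d**2).sum(axis=1)
    len2 = np.where(len2 < 1e-18, 1e-18, len2)
    # (n, m) projections clamped to the segments
    t = np.einsum("nmk,mk->nm", points[:, None, :] - p0[None, :, :], d) / len2
    t = np.clip(t, 0.0, 1.0)
    closest = p0[None, :, :] + t[:, :, None] * d[None, :, :]
    dist = np.linalg.norm(points[:, None, :] - closest, axis=2)
    return dist.min(axis=1)


def seed_stalk_distances(
    seeds: list[SeedInstance], stem_polyline_mm: np.ndarray
) -> dict[str, float]:
    """Min/mean/max Euclidean distance (mm) from seed centroids to the rachis polyline."""
    if not seeds:
        return {
            "MinDistanceSeedMainStalk": np.nan,
            "AvgDistanceSeedMainStalk": np.nan,
            "MaxDistanceSeedMainStalk": np.nan,
        }
    centroids = np.array([s.centroid_mm for s in seeds])
    dists = point_to_polyline_distance(centroids, np.asarray(stem_polyline_mm, float))
    return {
        "MinDistanceSeedMainStalk": float(dists.min()),
        "AvgDistanceSeedMainStalk": float(dists.mean()),
        "MaxDistanceSeedMainStalk": float(dists.max()),
    }
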