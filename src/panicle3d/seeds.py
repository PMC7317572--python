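"""Seed instance segmentation and per-seed morphology.

Seeds (caryopses) are denser than branch tissue, so a second, higher
threshold isolates them.  Segmentation then proceeds in a fixed order:

1. connected components above the seed threshold (26-connectivity);
2. noise removal — pieces smaller than one-eighth of the mean component
   volume are discarded;
3. splitting of touching seeds by morphological opening: each component
   is eroded by a ball, the surviving cores are labeled, and every
   original voxel is re-assigned to its nearest core, so the output is
   an exact partition of the component;
4. shape-outlier removal — pieces whose covariance major/minor axis
   ratio exceeds a cutoff (very long fragments of branch) are dropped.

Morphology is measured on up to 100 seeds sampled by rachis position
(10 z-bins × 10 seeds above the bin's 25th volume percentile, avoiding
underdeveloped seeds): moment-based ellipsoid fits, two elongation/
flatness variants, and a rotation- and scale-invariant radius histogram
over ~1000 uniformly distributed directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EllipsoidFitError
from .panicle import covariance_shape_ratios
from .volume import VoxelVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)

#: Default seed segmentation threshold on the standardized scale
#: (above branch tissue, below seed density).
SEED_THRESHOLD = 750.0

DEFAULT_OPENING_RADIUS = 2
DEFAULT_MAX_AXIS_RATIO = 4.0


@dataclass
class EllipsoidFit:
    """Moment-matched ellipsoid of a voxel set.

    ``semi_axes`` are sorted a ≥ b ≥ c (mm); ``orientation`` has the
    corresponding axis directions as columns; ``fit_error`` is the mean
    absolute radial distance (mm) between the surface voxels and the
    ellipsoid surface.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray
    fit_error: float


@dataclass
class SeedInstance:
    """One labeled seed: its voxels plus derived morphology."""

    label: int
    voxels: np.ndarray  # (n, 3) integer (z, y, x)
    voxel_edge: float  # µm
    ellipsoid: EllipsoidFit | None = None
    radius_hist: np.ndarray | None = None

    @property
    def voxel_mm(self) -> float:
        return self.voxel_edge / 1000.0

    @property
    def centroid_mm(self) -> np.ndarray:
        """Centroid in mm, (z, y, x) order."""
        return self.voxels.mean(axis=0) * self.voxel_mm

    @property
    def volume_mm3(self) -> float:
        return self.voxels.shape[0] * self.voxel_mm**3


def _local_mask(coords: np.ndarray, pad: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Dense boolean mask of a coordinate set within its padded bounding box."""
    origin = coords.min(axis=0) - pad
    shape = coords.max(axis=0) - origin + pad + 1
    mask = np.zeros(shape, dtype=bool)
    local = coords - origin
    mask[local[:, 0], local[:, 1], local[:, 2]] = True
    return mask, origin


def segment_seeds(
    vol: VoxelVolume,
    seed_threshold: float = SEED_THRESHOLD,
    opening_radius: int = DEFAULT_OPENING_RADIUS,
    max_axis_ratio: float = DEFAULT_MAX_AXIS_RATIO,
) -> tuple[np.ndarray, list[SeedInstance]]:
    """Full seed segmentation: threshold → noise filter → split → outlier filter.

    Returns the labeled volume (int32, 0 = background, seeds 1..N) and
    the corresponding :class:`SeedInstance` list.
    """
    fg = vol.intensities > seed_threshold
    labels_out = np.zeros(vol.shape, dtype=np.int32)
    if not fg.any():
        warnings.warn("no voxels above the seed threshold; zero seeds", stacklevel=2)
        return labels_out, []
    lab, n = ndimage.label(fg, structure=_CONN26)
    components = [np.argwhere(lab == i) for i in range(1, n + 1)]
    components = filter_noise_components(components)
    split: list[np.ndarray] = []
    for comp in components:
        split.extend(split_touching_seeds(comp, opening_radius))
    kept = filter_shape_outliers(split, max_axis_ratio)
    seeds = []
    for i, coords in enumerate(kept, start=1):
        labels_out[coords[:, 0], coords[:, 1], coords[:, 2]] = i
        seeds.append(SeedInstance(i, coords, vol.voxel_edge))
    return labels_out, seeds


def filter_noise_components(components: list[np.ndarray]) -> list[np.ndarray]:
    """Drop pieces smaller than one-eighth of the mean component volume.

    The mean is computed once over all input components.
    """
    if not components:
        return components
    sizes = np.array([len(c) for c in components], dtype=float)
    cutoff = sizes.mean() / 8.0
    return [c for c, s in zip(components, sizes) if s >= cutoff]


def split_touching_seeds(coords: np.ndarray, opening_radius: int = DEFAULT_OPENING_RADIUS
                         ) -> list[np.ndarray]:
    """Split a component of touching seeds by opening + nearest-core assignment.

    Erode by a ball of ``opening_radius``; if ≥ 2 cores survive, every
    voxel of the original component is assigned to the nearest core, so
    the outputs partition the input exactly.  If erosion leaves zero or
    one core the component is returned unchanged.
    """
    from skimage.morphology import ball

    if opening_radius < 1:
        return [coords]
    mask, origin = _local_mask(coords, pad=1)
    eroded = ndimage.binary_erosion(mask, structure=ball(opening_radius))
    cores, n_cores = ndimage.label(eroded, structure=_CONN26)
    if n_cores <= 1:
        return [coords]
    # nearest-core label for every voxel in the padded box
    _, (iz, iy, ix) = ndimage.distance_transform_edt(cores == 0, return_indices=True)
    assigned = cores[iz, iy, ix]
    local = coords - origin
    labels = assigned[local[:, 0], local[:, 1], local[:, 2]]
    return [coords[labels == k] for k in range(1, n_cores + 1) if (labels == k).any()]


def filter_shape_outliers(components: list[np.ndarray],
                          max_axis_ratio: float = DEFAULT_MAX_AXIS_RATIO
                          ) -> list[np.ndarray]:
    """Remove very long pieces: covariance axis ratio a/c > ``max_axis_ratio``.

    Eigenvalues get a 1/12-voxel² floor (the variance of a single voxel)
    so one-voxel-thick sheets are rated by their true aspect.
    """
    kept = []
    for coords in components:
        cov = np.cov(coords.T.astype(float)) if len(coords) > 1 else np.zeros((3, 3))
        lam = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1] + 1.0 / 12.0
        ratio = float(np.sqrt(lam[0] / lam[-1]))
        if ratio <= max_axis_ratio:
            kept.append(coords)
    return kept


def sample_seeds(
    seeds: list[SeedInstance],
    panicle_z_range: tuple[float, float],
    rng: np.random.Generator | int | None = None,
    n_bins: int = 10,
    per_bin: int = 10,
) -> list[SeedInstance]:
    """Sample up to ``n_bins × per_bin`` seeds stratified along the rachis.

    The panicle is divided into ``n_bins`` equal-height z-bins (mm range
    of the panicle mask); within each bin, candidates are the seeds with
    volume strictly above the bin's 25th volume percentile (linear-
    interpolation convention), from which ``per_bin`` are drawn without
    replacement.
    """
    rng = np.random.default_rng(rng)
    z_lo, z_hi = panicle_z_range
    edges = np.linspace(z_lo, z_hi, n_bins + 1)
    zs = np.array([s.centroid_mm[0] for s in seeds])
    vols = np.array([s.volume_mm3 for s in seeds])
    chosen: list[SeedInstance] = []
    for b in range(n_bins):
        if b < n_bins - 1:
            in_bin = (zs >= edges[b]) & (zs < edges[b + 1])
        else:
            in_bin = (zs >= edges[b]) & (zs <= edges[b + 1])
        idx = np.nonzero(in_bin)[0]
        if idx.size == 0:
            continue
        q25 = np.percentile(vols[idx], 25)
        candidates = idx[vols[idx] > q25]
        if candidates.size == 0:
            continue
        take = min(per_bin, candidates.size)
        picked = rng.choice(candidates, size=take, replace=False)
        chosen.extend(seeds[i] for i in sorted(picked))
    return chosen


def fit_ellipsoid(seed: SeedInstance) -> EllipsoidFit:
    """Moment-based ellipsoid fit: covariance eigendecomposition scaled by
    sqrt(5·λ) so a uniform solid ellipsoid is recovered exactly."""
    coords = seed.voxels.astype(float)
    if coords.shape[0] < 20:
        raise EllipsoidFitError(f"seed {seed.label}: {coords.shape[0]} voxels < 20")
    mm = seed.voxel_mm
    center = coords.mean(axis=0)
    cov = np.cov(coords.T)
    lam, vec = np.linalg.eigh(cov)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    if lam[-1] <= 1e-9:
        raise EllipsoidFitError(f"seed {seed.label}: degenerate covariance")
    semi_axes = np.sqrt(5.0 * lam) * mm
    fit_error = _surface_fit_error(seed, center, semi_axes / mm, vec) * mm
    return EllipsoidFit(center * mm, semi_axes, vec, float(fit_error))


def _surface_fit_error(seed: SeedInstance, center: np.ndarray,
                       semi_axes_vox: np.ndarray, rot: np.ndarray) -> float:
    """Mean |radial distance − ellipsoid radius| over surface voxels (voxel units)."""
    mask, origin = _local_mask(seed.voxels, pad=1)
    interior = ndimage.binary_erosion(mask)
    surface = np.argwhere(mask & ~interior) + origin
    u = surface.astype(float) - center
    d = np.linalg.norm(u, axis=1)
    d = np.where(d < 1e-9, 1e-9, d)
    w = (u / d[:, None]) @ rot  # direction in the ellipsoid frame
    r_dir = 1.0 / np.sqrt(((w / semi_axes_vox) ** 2).sum(axis=1))
    return float(np.abs(d - r_dir).mean())


def elongation_flatness(seed: SeedInstance) -> tuple[float, float, float, float]:
    """Seed elongation/flatness by both conventions.

    Covariance method: sqrt(λ2/λ1), sqrt(λ3/λ2); ellipsoid method: b/a,
    c/b from the fitted semi-axes.  All four lie in (0, 1].
    """
    elong_cov, flat_cov = covariance_shape_ratios(seed.voxels)
    fit = seed.ellipsoid if seed.ellipsoid is not None else fit_ellipsoid(seed)
    a, b, c = fit.semi_axes
    return elong_cov, flat_cov, float(b / a), float(c / b)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` nearly uniformly distributed unit vectors (Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / phi
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([z, r * np.sin(theta), r * np.cos(theta)])


def radius_histogram(seed: SeedInstance, n_directions: int = 1000,
                     n_bins: int = 10) -> np.ndarray:
    """Histogram of the directional radius, normalized by its mean.

    For each of ``n_directions`` uniformly distributed directions the
    radius is the distance from the centroid to the farthest surface
    voxel within a small angular cone around the direction (the cone
    covers ~1.5 lattice spacings, so every direction sees the digital
    surface even when directions outnumber surface voxels).  Radii are
    divided by their mean (scale invariance) and binned into ``n_bins``
    equal bins over [0.5, 1.5] of the normalized radius, outliers
    clipped to the end bins; the result sums to 1.
    """
    coords = seed.voxels.astype(float)
    centroid = coords.mean(axis=0)
    ci = tuple(np.round(centroid).astype(int))
    if not (seed.voxels == np.array(ci)).all(axis=1).any():
        warnings.warn(
            f"seed {seed.label}: centroid outside the voxel set; "
            "using farthest-intersection radii", stacklevel=2,
        )
    mask, origin = _local_mask(seed.voxels, pad=1)
    interior = ndimage.binary_erosion(mask)
    surface = np.argwhere(mask & ~interior) + origin
    u = surface.astype(float) - centroid
    norms = np.linalg.norm(u, axis=1)
    keep = norms > 1e-9
    u, norms = u[keep], norms[keep]
    dirs = fibonacci_sphere(n_directions)
    tree = cKDTree(u / norms[:, None])
    cone = 1.5 * np.sqrt(4.0 * np.pi / n_directions)  # chord ≈ angle
    hits = tree.query_ball_point(dirs, r=cone, workers=1)
    nearest = tree.query(dirs, workers=1)[1]
    radius = np.array([
        norms[h].max() if h else norms[nearest[i]]
        for i, h in enumerate(hits)
    ])
    radius = radius / radius.mean()
    edges = np.linspace(0.5, 1.5, n_bins + 1)
    clipped = np.clip(radius, 0.5, np.nextafter(1.5, 0.0))
    hist, _ = np.histogram(clipped, bins=edges)
    return hist / hist.sum()


def seed_summary(
    seeds: list[SeedInstance],
    sampled: list[SeedInstance],
    panicle_depth_mm: float,
) -> dict[str, float]:
    """The 19 seed-morphology traits (counts, volumes, and means over the
    ≤100 sampled seeds; the panicle radius histogram is the renormalized
    mean of per-seed histograms)."""
    out: dict[str, float] = {}
    out["SeedNumber"] = float(len(seeds))
    out["SeedNumberPerDepth"] = len(seeds) / panicle_depth_mm
    total = float(sum(s.volume_mm3 for s in seeds))
    out["SeedTotalVolume"] = total
    out["SeedAvgVolume"] = total / len(seeds) if seeds else np.nan
    if not seeds:
        for k in ("SeedNumberPerDepth", "SeedTotalVolume", "SeedAvgVolume"):
            out[k] = np.nan
        out["SeedTotalVolume"] = 0.0
    shape_keys = ("SeedElongation_cov", "SeedFlatness_cov",
                  "SeedElongation_ell", "SeedFlatness_ell", "SeedEllipsoidError")
    if sampled:
        quads, errs, hists = [], [], []
        for s in sampled:
            if s.ellipsoid is None:
                s.ellipsoid = fit_ellipsoid(s)
            if s.radius_hist is None:
                s.radius_hist = radius_histogram(s)
            quads.append(elongation_flatness(s))
            errs.append(s.ellipsoid.fit_error)
            hists.append(s.radius_hist)
        mean_quad = np.mean(quads, axis=0)
        for k, v in zip(shape_keys[:4], mean_quad):
            out[k] = float(v)
        out["SeedEllipsoidError"] = float(np.mean(errs))
        mean_hist = np.mean(hists, axis=0)
        mean_hist = mean_hist / mean_hist.sum()
        for i, v in enumerate(mean_hist, start=1):
            out[f"SeedshapeRhist{i}"] = float(v)
    else:
        for k in shape_keys:
            out[k] = np.nan
        for i in range(1, 11):
            out[f"SeedshapeRhist{i}"] = np.nan
    return out
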