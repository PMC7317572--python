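"""Synthetic panicle phantoms and synthetic trait tables.

Phantoms emulate the geometry a CT scan of a cereal inflorescence
presents to the pipeline: a vertical tapered stalk (optionally gently
curved), straight primary branches inserted at configured node heights,
angles and lengths, and bright ellipsoidal seeds attached along the
branches, optionally in touching pairs.  Intensities follow the
standardized scale (air 0, plant tissue below the seed threshold, seeds
above it) with additive Gaussian noise.  Every voxel's provenance is
recorded in a label map, and the returned ground truth carries exact
seed, branch, node and internode geometry, which makes phantom recovery
checkable trait by trait.

The default scale places the voxel edge at 214 µm — the working
resolution of the skeleton stage of a ~107 µm scan after 2×
downsampling — with a 60 mm (small) panicle, keeping default grids
well under 512³.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .volume import VoxelVolume

GOLDEN_ANGLE_DEG = 137.50776405003785


@dataclass
class NodeSpec:
    """One rachis node: insertion position and branch geometry."""

    arc_position: float  # mm along the stalk from its base
    branch_count: int = 1
    branch_length: float = 22.0  # mm
    angle: float = 40.0  # degrees from the vertical
    azimuths: tuple[float, ...] | None = None  # degrees; default golden-angle spread


@dataclass
class PhantomSpec:
    """Geometry, intensity and randomness of one synthetic panicle."""

    stalk_base_radius: float = 2.5  # mm
    stalk_tip_radius: float = 1.2  # mm
    height: float = 60.0  # mm
    curvature: float = 0.0  # lateral apex offset, mm
    nodes: list[NodeSpec] | None = None
    seeds_per_branch: int = 8
    seed_semi_axes: tuple[float, float, float] = (1.4, 1.0, 0.8)  # mm
    seed_jitter: float = 0.08  # fractional SD on the semi-axes
    touching_prob: float = 0.1
    branch_radius: float = 0.7  # mm
    air_intensity: float = 0.0
    branch_intensity: float = 600.0
    seed_intensity: float = 900.0
    noise_sd: float = 30.0
    voxel_edge: float = 214.0  # µm
    rng_seed: int = 0
    margin: float = 2.0  # mm of air around the geometry

    def resolved_nodes(self) -> list[NodeSpec]:
        if self.nodes is not None:
            return self.nodes
        arcs = np.linspace(0.18 * self.height, 0.85 * self.height, 8)
        return [NodeSpec(float(a)) for a in arcs]


@dataclass
class GroundTruth:
    """Exact geometry behind a rendered phantom."""

    seeds: list[dict]  # center (z,y,x mm), semi_axes (mm), orientation, label
    branches: list[dict]  # node_arc, node_z, length, tip_angle, azimuth
    internode_lengths: np.ndarray  # mm, between consecutive distinct nodes
    stalk: dict  # base_point, base/tip radius, height
    label_map: np.ndarray = field(repr=False)  # 0 air, 1 stalk, 2 branch, 10+i seeds

    @property
    def seed_count(self) -> int:
        return len(self.seeds)

    @property
    def branch_count(self) -> int:
        return len(self.branches)


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w


def generate_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Render a phantom volume and its exhaustive ground truth."""
    rng = np.random.default_rng(spec.rng_seed)
    mm = spec.voxel_edge / 1000.0
    nodes = spec.resolved_nodes()

    # --- plan geometry in mm, (z, y, x) with the stalk base at the origin
    branches = []
    az_counter = 0
    for node in nodes:
        for j in range(node.branch_count):
            if node.azimuths is not None:
                az = node.azimuths[j % len(node.azimuths)]
            else:
                az = (az_counter * GOLDEN_ANGLE_DEG) % 360.0
            az_counter += 1
            th, ph = np.radians(node.angle), np.radians(az)
            u = np.array([np.cos(th), np.sin(th) * np.sin(ph), np.sin(th) * np.cos(ph)])
            branches.append({
                "node_arc": node.arc_position,
                "length": node.branch_length,
                "tip_angle": node.angle,
                "azimuth": az,
                "_u": u,
            })

    def stalk_center(z: float) -> np.ndarray:
        t = np.clip(z / spec.height, 0.0, 1.0)
        return np.array([z, spec.curvature * t**2, 0.0])

    def stalk_radius(z: float) -> float:
        t = np.clip(z / spec.height, 0.0, 1.0)
        return spec.stalk_base_radius + t * (spec.stalk_tip_radius - spec.stalk_base_radius)

    # seed placement with collision avoidance: surfaces must stay ≥ 2 voxels
    # apart (so segmentation can recover every seed as its own component),
    # using the directional ellipsoid radius along the center-center line
    a0 = max(spec.seed_semi_axes)
    seeds: list[dict] = []

    def _radius_along(axes: np.ndarray, rot: np.ndarray, d: np.ndarray) -> float:
        w = d @ rot
        return float(1.0 / np.sqrt(((w / axes) ** 2).sum()))

    def try_place(center: np.ndarray, axes: np.ndarray, rot: np.ndarray,
                  partner_of: int | None = None) -> bool:
        for i, other in enumerate(seeds):
            if partner_of is not None and i == partner_of:
                continue
            delta = center - other["center"]
            dist = float(np.linalg.norm(delta))
            if dist < 1e-9:
                return False
            d = delta / dist
            gap = (dist - _radius_along(axes, rot, d)
                   - _radius_along(other["semi_axes"], other["orientation"], d))
            if gap < 2.2 * mm:
                return False
        seeds.append({"center": center, "semi_axes": axes, "orientation": rot})
        return True

    for br in branches:
        p0 = stalk_center(br["node_arc"])
        u = br["_u"]
        v, w = _orthonormal_frame(u)
        s_min = stalk_radius(br["node_arc"]) + a0 + 1.0
        s_max = br["length"] - a0 * 0.8
        if s_max <= s_min or spec.seeds_per_branch == 0:
            br["_seed_arcs"] = []
            continue
        arcs = np.linspace(s_min, s_max, spec.seeds_per_branch)
        for si, s in enumerate(arcs):
            base_side = [v, -v, w, -w][si % 4]
            axes = np.array(spec.seed_semi_axes) * np.clip(
                1.0 + spec.seed_jitter * rng.standard_normal(3), 0.7, 1.3)
            axes = np.sort(axes)[::-1]
            rot = _seed_rotation(u, rng)
            placed_ok = False
            for _attempt in range(8):  # re-draw the side angle on collision
                ang = rng.uniform(-0.4, 0.4)
                side = np.cos(ang) * base_side + np.sin(ang) * np.cross(u, base_side)
                # shallow attachment: the seed overlaps the branch tube by only
                # ~0.2 of its minor semi-axis, so digital seed removal leaves
                # the branch (and its skeleton) nearly intact
                center = p0 + s * u + side * (spec.branch_radius + 0.8 * axes[2])
                if try_place(center, axes, rot):
                    placed_ok = True
                    break
            if not placed_ok:
                continue
            if rng.uniform() < spec.touching_prob:
                # partner sharing ≲ 10% volume, offset along the major axis
                axes2 = axes * np.clip(1.0 + spec.seed_jitter * rng.standard_normal(), 0.8, 1.2)
                delta = 0.75 * (axes[0] + axes2[0])
                center2 = center + rot[:, 0] * delta
                try_place(center2, axes2, rot, partner_of=len(seeds) - 1)

    # --- grid bounds
    pts = [stalk_center(0.0), stalk_center(spec.height)]
    rad = [spec.stalk_base_radius, spec.stalk_tip_radius]
    for br in branches:
        p0 = stalk_center(br["node_arc"])
        pts += [p0, p0 + br["length"] * br["_u"]]
        rad += [spec.branch_radius, spec.branch_radius]
    for s in seeds:
        pts.append(s["center"])
        rad.append(float(s["semi_axes"].max()))
    pts = np.array(pts)
    rad = np.array(rad)[:, None]
    lo = (pts - rad).min(axis=0) - spec.margin
    hi = (pts + rad).max(axis=0) + spec.margin
    origin = lo  # mm position of voxel index (0, 0, 0)
    shape = np.ceil((hi - lo) / mm).astype(int) + 1
    if (shape > 512).any():
        warnings.warn(f"phantom grid {tuple(shape)} exceeds 512³; expanding anyway",
                      stacklevel=2)

    labels = np.zeros(shape, dtype=np.int32)
    nz, ny, nx = shape
    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    yy_mm = origin[1] + yy * mm
    xx_mm = origin[2] + xx * mm

    # stalk: per-slice disk around the (possibly curved) centerline
    for iz in range(nz):
        z = origin[0] + iz * mm
        if z < 0.0 or z > spec.height:
            continue
        c = stalk_center(z)
        r = stalk_radius(z)
        disk = (yy_mm - c[1]) ** 2 + (xx_mm - c[2]) ** 2 <= r**2
        labels[iz][disk] = 1

    for br in branches:
        p0 = stalk_center(br["node_arc"])
        p1 = p0 + br["length"] * br["_u"]
        _paint_tube(labels, origin, mm, p0, p1, spec.branch_radius, value=2,
                    only_empty=True)

    for i, s in enumerate(seeds):
        s["label"] = 10 + i
        _paint_ellipsoid(labels, origin, mm, s["center"], s["semi_axes"],
                         s["orientation"], value=10 + i)

    intensities = np.full(shape, spec.air_intensity, dtype=np.float32)
    intensities[(labels == 1) | (labels == 2)] = spec.branch_intensity
    intensities[labels >= 10] = spec.seed_intensity
    if spec.noise_sd > 0:
        intensities += rng.normal(0.0, spec.noise_sd, size=shape).astype(np.float32)

    node_arcs = sorted({br["node_arc"] for br in branches})
    internodes = np.diff(node_arcs)
    gt_branches = [
        {k: br[k] for k in ("node_arc", "length", "tip_angle", "azimuth")}
        | {"node_z": stalk_center(br["node_arc"])[0] - origin[0],
           "node_point": stalk_center(br["node_arc"]) - origin,
           "direction": br["_u"]}
        for br in branches
    ]
    gt_seeds = [
        {"center": s["center"] - origin, "semi_axes": s["semi_axes"],
         "orientation": s["orientation"], "label": s["label"]}
        for s in seeds
    ]
    truth = GroundTruth(
        seeds=gt_seeds,
        branches=gt_branches,
        internode_lengths=internodes,
        stalk={
            "base_point": -origin,
            "base_radius": spec.stalk_base_radius,
            "tip_radius": spec.stalk_tip_radius,
            "height": spec.height,
        },
        label_map=labels,
    )
    vol = VoxelVolume(intensities, spec.voxel_edge, name=f"phantom-{spec.rng_seed}")
    return vol, truth


def _paint_tube(labels: np.ndarray, origin: np.ndarray, mm: float,
                p0: np.ndarray, p1: np.ndarray, radius: float, value: int,
                only_empty: bool = False) -> None:
    lo = np.floor((np.minimum(p0, p1) - radius - origin) / mm).astype(int)
    hi = np.ceil((np.maximum(p0, p1) + radius - origin) / mm).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, labels.shape)
    if (hi <= lo).any():
        return
    grid = np.moveaxis(np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], 0, -1)
    pts = origin + grid * mm
    d = p1 - p0
    len2 = float(d @ d)
    t = np.clip(((pts - p0) @ d) / len2, 0.0, 1.0)
    closest = p0 + t[..., None] * d
    inside = ((pts - closest) ** 2).sum(-1) <= radius**2
    region = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if only_empty:
        inside &= region == 0
    region[inside] = value


def _paint_ellipsoid(labels: np.ndarray, origin: np.ndarray, mm: float,
                     center: np.ndarray, axes: np.ndarray, rot: np.ndarray,
                     value: int) -> None:
    amax = float(axes.max())
    lo = np.maximum(np.floor((center - amax - origin) / mm).astype(int), 0)
    hi = np.minimum(np.ceil((center + amax - origin) / mm).astype(int) + 1, labels.shape)
    if (hi <= lo).any():
        return
    grid = np.moveaxis(np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]], 0, -1)
    w = (origin + grid * mm - center) @ rot
    inside = ((w / axes) ** 2).sum(-1) <= 1.0
    labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][inside] = value


def _seed_rotation(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rotation with the major axis near the branch direction (small jitter)."""
    major = u + 0.1 * rng.standard_normal(3)
    major /= np.linalg.norm(major)
    v, w = _orthonormal_frame(major)
    ang = rng.uniform(0.0, 2.0 * np.pi)
    b = np.cos(ang) * v + np.sin(ang) * w
    c = np.cross(major, b)
    return np.column_stack([major, b, c])


# ---------------------------------------------------------------------------
# synthetic trait tables

def generate_trait_table(
    n_per_race: int = 11,
    effect_matrix: np.ndarray | dict | None = None,
    noise_sd: float = 1.0,
    rng_seed: int | None = 0,
    n_replicates: int = 1,
    equicorrelation: float = 0.0,
):
    """Draw a synthetic accessions × 77-trait table with known race structure.

    Latent trait values are multivariate normal with a shared covariance
    (identity scaled by ``noise_sd``², optionally equicorrelated) and
    race-specific mean shifts given by ``effect_matrix`` (5 × 77 array,
    or a ``{race: {feature: shift}}`` mapping, in SD units; ``None`` =
    the global null).  The four 10-bin histogram blocks are passed
    through a softmax so every histogram row is a valid distribution.
    """
    import pandas as pd

    from .catalog import ALL_FEATURES, HISTOGRAM_GROUPS, RACES

    rng = np.random.default_rng(rng_seed)
    p = len(ALL_FEATURES)
    if effect_matrix is None:
        effects = np.zeros((len(RACES), p))
    elif isinstance(effect_matrix, dict):
        effects = np.zeros((len(RACES), p))
        col = {f: j for j, f in enumerate(ALL_FEATURES)}
        for r, feats in effect_matrix.items():
            for f, v in feats.items():
                effects[RACES.index(r), col[f]] = v
    else:
        effects = np.asarray(effect_matrix, dtype=float)
        if effects.shape != (len(RACES), p):
            raise ValueError(f"effect_matrix must be {(len(RACES), p)}, got {effects.shape}")

    rows = []
    for ri, race in enumerate(RACES):
        for a in range(n_per_race):
            accession = f"{race[:3].upper()}{a:03d}"
            latent_mean = effects[ri]
            for rep in range(n_replicates):
                z = rng.standard_normal(p)
                if equicorrelation > 0.0:
                    shared = rng.standard_normal()
                    z = np.sqrt(1 - equicorrelation) * z + np.sqrt(equicorrelation) * shared
                vals = latent_mean + noise_sd * z
                rows.append({"accession": accession, "replicate": rep, "race": race}
                            | dict(zip(ALL_FEATURES, vals)))
    df = pd.DataFrame(rows)
    # histogram blocks → valid distributions via softmax
    for cols in HISTOGRAM_GROUPS.values():
        block = np.exp(df[cols].to_numpy())
        df[cols] = block / block.sum(axis=1, keepdims=True)
    return df
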