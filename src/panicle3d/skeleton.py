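"""Curve-skeleton extraction and branch-architecture traits.

The seedless panicle is downsampled, thresholded and hole-filled, then
thinned to a one-voxel-wide, homotopy-preserving curve skeleton whose
vertices carry a radius (the Euclidean distance transform of the mask).
Spurious twigs — thinning artifacts shorter than a multiple of the
local radius — are pruned iteratively, which leaves genuine branches
(much longer than the tube radius) untouched.

The rachis (main stalk) is the thickest structure: a hysteresis
threshold on the vertex radii selects a high-radius core, grows it
through a permissive lower threshold, and the stem is the
bottleneck-widest path (maximizing the minimum radius en route) between
the lowest and highest vertices of that region.  Stem junctions with
off-stem subtrees form nodes; from each node, the branch tracer walks
outward choosing at every junction the geometrically straightest
continuation.  Node positions are refined by extrapolating the branch
centerline back to its closest approach with the stem polyline, which
removes the junction-displacement bias that voxel thinning introduces
near a thick stalk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage

from .errors import SegmentationError, StemError
from .volume import VoxelVolume

_CONN26 = np.ones((3, 3, 3), dtype=bool)

_NEIGHBOR_OFFSETS = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) > (0, 0, 0)
    ]
)  # 13 half-space offsets: each undirected pair counted once


@dataclass
class CurveSkeleton:
    """1D graph embedded in 3D with a per-vertex radius (all units mm)."""

    vertices: np.ndarray  # (n, 3) points, (z, y, x) mm
    radii: np.ndarray  # (n,)
    edges: np.ndarray  # (m, 2) vertex-index pairs
    _graph: nx.Graph | None = field(default=None, repr=False, compare=False)

    @property
    def graph(self) -> nx.Graph:
        if self._graph is None:
            g = nx.Graph()
            g.add_nodes_from(range(len(self.vertices)))
            g.add_edges_from(map(tuple, self.edges))
            self._graph = g
        return self._graph

    def arc_length(self, path: list[int]) -> float:
        pts = self.vertices[path]
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class StemPath:
    """The rachis as an ordered (bottom → top) simple path in the skeleton."""

    vertex_indices: list[int]
    polyline: np.ndarray  # (k, 3) mm
    length: float  # mm
    main_stalk_diameter: float  # mm
    median_radius: float  # mm


@dataclass
class Branch:
    """A primary branch: node on the stem plus its traced path."""

    node_vertex: int
    path: list[int]
    length: float  # mm, polyline arc length
    tip_angle: float  # degrees from the upward stem direction
    node_arc: float  # mm along the stem, after refinement/merging
    node_point: np.ndarray  # (3,) mm


def remove_seeds(vol: VoxelVolume, seed_labels: np.ndarray,
                 background: float = 0.0) -> VoxelVolume:
    """Digitally remove labeled seed voxels, leaving the seedless panicle."""
    out = vol.intensities.copy()
    out[seed_labels > 0] = background
    from dataclasses import replace

    return replace(vol, intensities=out)


def prepare_mask(vol: VoxelVolume, threshold: float = 300.0,
                 downsample: int = 2) -> tuple[np.ndarray, float]:
    """Downsample (mean pooling), threshold, keep the largest component and
    fill holes; returns ``(mask, voxel_edge_µm)`` at the coarse resolution."""
    from skimage.measure import block_reduce

    data = vol.intensities
    if downsample > 1:
        data = block_reduce(data, (downsample,) * 3, np.mean)
    mask = data > threshold
    if not mask.any():
        raise SegmentationError("no foreground after downsampling + threshold")
    labels, n = ndimage.label(mask, structure=_CONN26)
    if n > 1:
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        mask = labels == int(np.argmax(sizes))
    mask = ndimage.binary_fill_holes(mask)
    # a hollow stem cut open at the ends is not an enclosed 3D cavity;
    # fill per-slice so the rachis consolidates into one solid tube
    for z in range(mask.shape[0]):
        mask[z] = ndimage.binary_fill_holes(mask[z])
    return mask, vol.voxel_edge * downsample


def skeletonize_with_radius(mask: np.ndarray, voxel_edge: float,
                            prune_factor: float = 1.5) -> CurveSkeleton:
    """Thin the mask to a curve skeleton with a distance-transform radius.

    Homotopy-preserving 3D thinning yields a one-voxel-wide curve set;
    each vertex's radius is the EDT of the mask there (≥ half a voxel).
    Twigs shorter than ``prune_factor ×`` the radius at their supporting
    junction are removed iteratively.
    """
    from skimage.morphology import skeletonize

    # thinning sweeps are orientation dependent and can annihilate shapes in
    # grid-symmetric poses; retry under axis permutations/reflections
    skel = skeletonize(mask)
    if not skel.any():
        for fwd, back in (
            (lambda m: m.transpose(0, 2, 1), lambda m: m.transpose(0, 2, 1)),
            (lambda m: m[:, ::-1], lambda m: m[:, ::-1]),
            (lambda m: m[:, :, ::-1], lambda m: m[:, :, ::-1]),
        ):
            skel = back(skeletonize(np.ascontiguousarray(fwd(mask))))
            if skel.any():
                break
    if not skel.any():
        warnings.warn("mask too thin to skeletonize; using mask voxels", stacklevel=2)
        skel = mask.copy()
    edt = ndimage.distance_transform_edt(mask)
    coords = np.argwhere(skel)
    mm = voxel_edge / 1000.0
    radii = np.maximum(edt[tuple(coords.T)], 0.5) * mm
    index = {tuple(c): i for i, c in enumerate(coords)}
    edges = []
    for off in _NEIGHBOR_OFFSETS:
        nb = coords + off
        for i, c in enumerate(map(tuple, nb)):
            j = index.get(c)
            if j is not None:
                edges.append((i, j))
    edges = _reduce_triangles(coords, edges)
    skeleton = CurveSkeleton(coords * mm, radii, np.array(edges, dtype=int))
    return _prune_twigs(skeleton, prune_factor)


def _reduce_triangles(coords: np.ndarray, edges: list[tuple[int, int]]
                      ) -> list[tuple[int, int]]:
    """Drop the longest edge of every 3-cycle of the 26-adjacency graph.

    Diagonal steps make each voxel junction a small clique; the shortcut
    edges are redundant for connectivity and inflate vertex degrees.
    """
    g = nx.Graph()
    g.add_edges_from(edges)
    for tri in [c for c in nx.enumerate_all_cliques(g) if len(c) == 3]:
        a, b, c = tri
        if not (g.has_edge(a, b) and g.has_edge(b, c) and g.has_edge(a, c)):
            continue
        pairs = [(a, b), (b, c), (a, c)]
        lengths = [np.linalg.norm(coords[u] - coords[v]) for u, v in pairs]
        u, v = pairs[int(np.argmax(lengths))]
        g.remove_edge(u, v)
    return list(g.edges)


def _prune_twigs(skel: CurveSkeleton, prune_factor: float) -> CurveSkeleton:
    g = skel.graph.copy()
    pos, rad = skel.vertices, skel.radii
    changed = True
    while changed:
        changed = False
        leaves = [v for v in g.nodes if g.degree(v) == 1]
        for leaf in leaves:
            if leaf not in g or g.degree(leaf) != 1:
                continue
            path = [leaf]
            cur, prev = leaf, None
            while g.degree(cur) <= 2:
                nxts = [u for u in g.neighbors(cur) if u != prev]
                if not nxts:
                    break
                prev, cur = cur, nxts[0]
                if g.degree(cur) <= 2:
                    path.append(cur)
                else:
                    break
            if g.degree(cur) <= 2:
                continue  # chain ends at another leaf: keep (would disconnect)
            arc = float(np.linalg.norm(np.diff(pos[path + [cur]], axis=0), axis=1).sum())
            if arc < prune_factor * rad[cur]:
                g.remove_nodes_from(path)
                changed = True
    keep = sorted(g.nodes)
    remap = {v: i for i, v in enumerate(keep)}
    new_edges = np.array([(remap[u], remap[v]) for u, v in g.edges], dtype=int)
    return CurveSkeleton(pos[keep], rad[keep], new_edges)


def identify_stem(skel: CurveSkeleton, high_percentile: float = 85.0,
                  low_percentile: float = 60.0) -> StemPath:
    """Hysteresis on the radius: grow the thick core through a permissive
    threshold, then take the bottleneck-widest bottom-to-top path."""
    r = skel.radii
    high = np.percentile(r, high_percentile)
    core = np.nonzero(r >= high)[0]
    if core.size == 0:
        raise StemError("no vertices above the high radius threshold")
    g = skel.graph
    # the permissive threshold must sit below the stalk's own radius
    # variation; cap it relative to the core threshold and back off
    # further if the region still comes apart
    low0 = min(np.percentile(r, low_percentile), 0.6 * high)
    sub = None
    for low in (low0, 0.45 * high, 0.3 * high, float(r.min())):
        permissive = g.subgraph(np.nonzero(r >= low)[0])
        region: set[int] = set()
        for comp in nx.connected_components(permissive):
            if any(v in comp for v in core):
                region |= comp
        cand = g.subgraph(region)
        # endpoints anchored on the core: the permissive region may reach
        # branch tips, which can overtop a tapering stalk apex
        zs = skel.vertices[core, 0]
        bottom = int(core[int(np.argmin(zs))])
        top = int(core[int(np.argmax(zs))])
        if nx.has_path(cand, bottom, top):
            sub = cand
            break
    if sub is None:
        raise StemError("thick region disconnected bottom-to-top")
    # bottleneck-widest path via the maximum spanning tree on min-radius weights
    w = nx.Graph()
    for u, v in sub.edges:
        w.add_edge(u, v, weight=min(r[u], r[v]) + 1e-9 * (r[u] + r[v]))
    mst = nx.maximum_spanning_tree(w)
    path = nx.shortest_path(mst, bottom, top)
    if skel.vertices[path[0], 0] > skel.vertices[path[-1], 0]:
        path = path[::-1]
    path = _extend_stem(skel, path)
    # voxel paths zigzag at the grid scale, which inflates arc lengths and
    # makes local tangents noisy; a short moving average recovers the
    # smooth rachis centerline
    polyline = _smooth_polyline(skel.vertices[path], window=4)
    # thinning retracts each end of a tube by about one local radius;
    # compensate so the reported length matches the physical stalk
    length = float(np.linalg.norm(np.diff(polyline, axis=0), axis=1).sum()
                   + r[path[0]] + r[path[-1]])
    med_r = float(np.median(r[path]))
    return StemPath(path, polyline, length, 2.0 * med_r, med_r)


def _extend_stem(skel: CurveSkeleton, path: list[int],
                 radius_fraction: float = 0.5) -> list[int]:
    """Continue the stem past the thick core toward both stalk ends.

    The core covers only the thickest stretch of a tapering rachis.
    From each end, consider the skeleton vertices whose radius stays a
    reasonable fraction of the stem's median (side branches, being much
    thinner, drop out), find the extreme-z vertex still reachable there,
    and append the bottleneck-widest path to it.  The radius is smoothed
    by a neighborhood maximum first so that one-vertex dips (seed scars,
    junction artifacts) do not sever the stalk.
    """
    g = skel.graph
    r = skel.radii
    r_eff = r.copy()
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if nbrs:
            r_eff[v] = max(r[v], r[nbrs].max())
    floor = radius_fraction * float(np.median(r[path]))
    allowed = set(np.nonzero(r_eff >= floor)[0])
    for upward in (True, False):
        end = path[-1] if upward else path[0]
        block = set(path) - {end}
        comp = {end}
        frontier = [end]
        while frontier:
            nxt_frontier = []
            for v in frontier:
                for u in g.neighbors(v):
                    if u in allowed and u not in comp and u not in block:
                        comp.add(u)
                        nxt_frontier.append(u)
            frontier = nxt_frontier
        zs = skel.vertices[list(comp), 0]
        members = list(comp)
        target = members[int(np.argmax(zs) if upward else np.argmin(zs))]
        if target == end:
            continue
        w = nx.Graph()
        sub = g.subgraph(comp)
        for u, v in sub.edges:
            w.add_edge(u, v, weight=min(r[u], r[v]))
        ext = nx.shortest_path(nx.maximum_spanning_tree(w), end, target)
        path = path + ext[1:] if upward else ext[::-1][:-1] + path
    return path


def _smooth_polyline(pts: np.ndarray, window: int = 4) -> np.ndarray:
    if len(pts) <= 2 * window + 1:
        return pts
    out = np.empty_like(pts)
    for i in range(len(pts)):
        lo, hi = max(0, i - window), min(len(pts), i + window + 1)
        out[i] = pts[lo:hi].mean(axis=0)
    return out


def _stem_arc_positions(stem: StemPath) -> np.ndarray:
    seg = np.linalg.norm(np.diff(stem.polyline, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _stem_up_direction(stem: StemPath, k: int) -> np.ndarray:
    """Local stem tangent near path position k, oriented upward (+z).

    The window spans a few stalk radii of arc on each side: junctions
    perturb the skeleton over about one radius, so shorter windows pick
    up spurious tilt.
    """
    arcs = _stem_arc_positions(stem)
    half = max(4.0 * stem.median_radius, 3.0)
    lo_arc, hi_arc = arcs[k] - half, arcs[k] + half
    # keep the window length when the stem ends truncate one side
    if lo_arc < arcs[0]:
        hi_arc += arcs[0] - lo_arc
        lo_arc = arcs[0]
    if hi_arc > arcs[-1]:
        lo_arc = max(arcs[0], lo_arc - (hi_arc - arcs[-1]))
        hi_arc = arcs[-1]
    lo = int(np.searchsorted(arcs, lo_arc))
    hi = min(int(np.searchsorted(arcs, hi_arc)), len(arcs) - 1)
    d = stem.polyline[hi] - stem.polyline[lo]
    n = np.linalg.norm(d)
    if n < 1e-9:
        return np.array([1.0, 0.0, 0.0])
    d = d / n
    return d if d[0] >= 0 else -d


def _closest_arc_on_stem(stem: StemPath, arcs: np.ndarray, point: np.ndarray,
                         direction: np.ndarray | None = None) -> tuple[float, np.ndarray]:
    """Stem arc position closest to a point, or to the line point + t·direction."""
    p0 = stem.polyline[:-1]
    d = np.diff(stem.polyline, axis=0)
    len2 = np.maximum((d**2).sum(1), 1e-18)
    if direction is None:
        t = np.clip(((point - p0) * d).sum(1) / len2, 0.0, 1.0)
        proj = p0 + t[:, None] * d
        dist = np.linalg.norm(proj - point, axis=1)
    else:
        # closest approach between each stem segment and the infinite line
        u = direction / np.linalg.norm(direction)
        best = None
        dist = np.full(len(p0), np.inf)
        t = np.zeros(len(p0))
        for i in range(len(p0)):
            ti, dd = _segment_line_closest(p0[i], d[i], point, u)
            t[i], dist[i] = ti, dd
        proj = p0 + t[:, None] * d
    i = int(np.argmin(dist))
    seg_len = np.sqrt(len2[i])
    return float(arcs[i] + t[i] * seg_len), proj[i]


def _segment_line_closest(a: np.ndarray, ab: np.ndarray, p: np.ndarray,
                          u: np.ndarray) -> tuple[float, float]:
    """Parameter on segment a + t·ab (t ∈ [0,1]) closest to the line p + s·u."""
    len2 = float(ab @ ab)
    if len2 < 1e-18:
        return 0.0, float(np.linalg.norm(np.cross(a - p, u)))
    w0 = a - p
    b = float(ab @ u)
    c = float(w0 @ u)
    denom = len2 - b * b
    if abs(denom) < 1e-12:
        t = 0.0  # parallel
    else:
        t = float((b * c - (w0 @ ab)) / denom)
    t = min(1.0, max(0.0, t))
    q = a + t * ab
    s = float((q - p) @ u)
    return t, float(np.linalg.norm(q - (p + s * u)))


def detect_nodes_and_branches(
    skel: CurveSkeleton,
    stem: StemPath,
    min_branch_len: float = 5.0,
    node_merge_dist: float = 2.0,
    refine_nodes: bool = True,
) -> list[Branch]:
    """Trace primary branches from stem junctions.

    From every stem vertex with an off-stem neighbor, walk outward
    choosing at each junction the continuation with the smallest turning
    angle, stop at a leaf (or on re-entering the stem), and accept the
    path as a primary branch if its arc length is at least
    ``min_branch_len`` (mm).  Node positions are refined by intersecting
    the extrapolated branch centerline with the stem, and nodes closer
    than ``node_merge_dist`` along the stem are merged (whorls).
    """
    g = skel.graph
    pos, rad = skel.vertices, skel.radii
    stem_set = set(stem.vertex_indices)
    arcs = _stem_arc_positions(stem)
    stem_pos_of = {v: i for i, v in enumerate(stem.vertex_indices)}
    visited: set[int] = set()
    branches: list[Branch] = []
    for k, v in enumerate(stem.vertex_indices):
        for w in g.neighbors(v):
            if w in stem_set or w in visited:
                continue
            path = _trace_branch(g, pos, v, w, stem_set, visited)
            arc_len = skel.arc_length(path)
            if arc_len < min_branch_len:
                continue
            free = _free_selection(skel, stem, path)
            up = _stem_up_direction(stem, k)
            tip_angle = _tip_angle(skel, path, up, free)
            node_arc, node_point = arcs[k], pos[v]
            if refine_nodes:
                refined = _refine_node(skel, stem, arcs, path, free)
                if refined is not None:
                    node_arc, node_point = refined
            branches.append(Branch(v, path, arc_len, tip_angle, node_arc, node_point))
    _merge_nodes(branches, node_merge_dist)
    return branches


def _trace_branch(g: nx.Graph, pos: np.ndarray, start: int, first: int,
                  stem_set: set[int], visited: set[int]) -> list[int]:
    path = [start, first]
    visited.add(first)
    while True:
        cur, prev = path[-1], path[-2]
        nxts = [u for u in g.neighbors(cur)
                if u != prev and u not in stem_set and u not in path[-8:]]
        nxts = [u for u in nxts if u not in visited or g.degree(u) == 1]
        if not nxts:
            break
        if len(nxts) == 1:
            nxt = nxts[0]
        else:
            back = max(0, len(path) - 4)
            incoming = pos[cur] - pos[path[back]]
            n = np.linalg.norm(incoming)
            incoming = incoming / n if n > 1e-12 else incoming
            best, best_cos = nxts[0], -2.0
            for u in nxts:
                d = pos[u] - pos[cur]
                dn = np.linalg.norm(d)
                cosang = float(incoming @ d / dn) if dn > 1e-12 else -1.0
                if cosang > best_cos:
                    best, best_cos = u, cosang
            nxt = best
        path.append(nxt)
        visited.add(nxt)
    return path


def _free_selection(skel: CurveSkeleton, stem: StemPath, path: list[int],
                    clearance: float = 1.3) -> np.ndarray:
    """Branch vertices clear of both bias zones: outside the stalk body
    (where thinning drags the junction along the stem) and short of the
    last ~1.5 tube radii (where the thinned tip deforms)."""
    from .spatial import point_to_polyline_distance

    pts = skel.vertices[path]
    dist = point_to_polyline_distance(pts, stem.polyline)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    tip_trim = max(1.5 * skel.radii[path[-1]], 0.6)
    return (dist > clearance * stem.median_radius) & (cum < cum[-1] - tip_trim)


def _fit_direction(window: np.ndarray) -> np.ndarray | None:
    """Total-least-squares line direction with one outlier-trimmed refit.

    Vertices dented by seed scars pull a plain fit; points whose distance
    to the first-pass line exceeds 2× the median residual are dropped
    once and the line refitted.
    """
    if len(window) < 2:
        return None

    def _tls(pts: np.ndarray) -> np.ndarray:
        t = np.linalg.svd(pts - pts.mean(axis=0), full_matrices=False)[2][0]
        return t if t @ (pts[-1] - pts[0]) >= 0 else -t

    tangent = _tls(window)
    if len(window) >= 8:
        center = window.mean(axis=0)
        rel = window - center
        resid = np.linalg.norm(rel - np.outer(rel @ tangent, tangent), axis=1)
        cut = 2.0 * max(float(np.median(resid)), 1e-6)
        keep = resid <= cut
        if 6 <= keep.sum() < len(window):
            tangent = _tls(window[keep])
    return tangent


def _tip_angle(skel: CurveSkeleton, path: list[int], up: np.ndarray,
               free: np.ndarray) -> float:
    """Angle between the distal branch tangent and the upward stem direction.

    The tangent is a straight-line fit to the clean (off-stalk,
    tip-trimmed) branch vertices, oriented toward the tip; single voxel
    steps are too quantized to define a direction, and the distal-most
    stretch is deformed by thinning, so the fit spans the whole clean
    region.
    """
    pts = skel.vertices[path]
    sel = pts[free] if free.sum() >= 4 else pts[max(0, len(pts) - 6):]
    tangent = _fit_direction(sel)
    if tangent is None:
        return float("nan")
    cosang = float(np.clip(tangent @ up, -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def _refine_node(skel: CurveSkeleton, stem: StemPath, arcs: np.ndarray,
                 path: list[int], free: np.ndarray
                 ) -> tuple[float, np.ndarray] | None:
    """Extrapolate the off-stalk part of the branch back to the stem axis.

    Thinning drags the skeleton junction along the stem away from the
    true insertion point by up to a stalk radius; fitting a line to the
    clean branch vertices and taking its closest approach to the stem
    polyline undoes that bias.
    """
    if free.sum() < 4:
        return None
    sel = skel.vertices[path][free]
    u = _fit_direction(sel)
    center = sel.mean(axis=0)
    arc0, point = _closest_arc_on_stem(stem, arcs, center, direction=u)
    # the stem polyline itself bulges toward the branch at the junction;
    # re-intersect with a local stem line fitted away from the junction
    r = stem.median_radius
    near = (np.abs(arcs - arc0) < 6.0 * max(r, 1.0)) & (np.abs(arcs - arc0) > 1.5 * r)
    if near.sum() >= 6:
        stem_pts = stem.polyline[near]
        us = _fit_direction(stem_pts)
        cs = stem_pts.mean(axis=0)
        # closest point on the stem line to the branch line
        w0 = cs - center
        b = float(us @ u)
        denom = 1.0 - b * b
        if abs(denom) > 1e-9:
            s = float((b * (w0 @ u) - (w0 @ us)) / denom)
            point = cs + s * us
            ref = int(np.argmin(np.abs(arcs - arc0)))
            arc0 = float(arcs[ref] + (point - stem.polyline[ref]) @ us)
    return arc0, point


def _merge_nodes(branches: list[Branch], node_merge_dist: float) -> None:
    """Cluster branch node arc-positions closer than ``node_merge_dist``;
    members of a cluster share the mean arc position (in place)."""
    if not branches:
        return
    order = np.argsort([b.node_arc for b in branches])
    clusters: list[list[int]] = [[order[0]]]
    for i in order[1:]:
        if branches[i].node_arc - branches[clusters[-1][-1]].node_arc <= node_merge_dist:
            clusters[-1].append(i)
        else:
            clusters.append([i])
    for cluster in clusters:
        mean_arc = float(np.mean([branches[i].node_arc for i in cluster]))
        for i in cluster:
            branches[i].node_arc = mean_arc


def branch_traits(branches: list[Branch], stem: StemPath,
                  panicle_depth: float) -> dict[str, float]:
    """The eight branch-architecture traits (lengths mm, angles degrees)."""
    out: dict[str, float] = {
        "PrimaryBranchNumber": float(len(branches)),
        "PrimaryBranchNumberPerDepth": len(branches) / panicle_depth,
        "MainStalkDiameter": stem.main_stalk_diameter,
    }
    if not branches:
        for k in ("FirstPrimaryBranchLength", "PrimaryBranchAvgLength",
                  "LongestInternodeLength", "SecondLongestInternodeLength",
                  "PrimaryBranchTipAngle"):
            out[k] = np.nan
        return out
    lowest = min(branches, key=lambda b: b.node_arc)
    out["FirstPrimaryBranchLength"] = lowest.length
    out["PrimaryBranchAvgLength"] = float(np.mean([b.length for b in branches]))
    out["PrimaryBranchTipAngle"] = float(np.nanmean([b.tip_angle for b in branches]))
    node_arcs = sorted(set(round(b.node_arc, 9) for b in branches))
    internodes = np.diff(node_arcs)
    if len(internodes) >= 1:
        srt = np.sort(internodes)[::-1]
        out["LongestInternodeLength"] = float(srt[0])
        out["SecondLongestInternodeLength"] = float(srt[1]) if len(srt) > 1 else np.nan
    else:
        out["LongestInternodeLength"] = np.nan
        out["SecondLongestInternodeLength"] = np.nan
    return out


def write_swc(skel: CurveSkeleton, stem: StemPath, branches: list[Branch],
              path: str) -> None:
    """Export the skeleton as SWC (id, type, x, y, z, radius, parent).

    Stem vertices get SWC type 1, branch vertices type 3, remaining
    skeleton vertices type 0; the tree is rooted at the stem bottom.
    """
    g = skel.graph
    types = np.zeros(len(skel.vertices), dtype=int)
    for b in branches:
        types[b.path] = 3
    types[stem.vertex_indices] = 1
    root = stem.vertex_indices[0]
    parent = {root: -1}
    order = [root]
    for u, v in nx.bfs_edges(g, root):
        parent[v] = u
        order.append(v)
    remap = {v: i + 1 for i, v in enumerate(order)}
    with open(path, "w") as fh:
        fh.write("# SWC export: type 1 = stem, 3 = primary branch\n")
        for v in order:
            z, y, x = skel.vertices[v]
            p = parent[v]
            fh.write(
                f"{remap[v]} {types[v]} {x:.4f} {y:.4f} {z:.4f} "
                f"{skel.radii[v]:.4f} {remap[p] if p != -1 else -1}\n"
            )
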