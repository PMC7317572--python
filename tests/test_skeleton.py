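"""Curve skeleton, stem identification and branch-architecture traits."""

from collections import Counter

import networkx as nx
import numpy as np
import pytest

from panicle3d import (
    Branch,
    CurveSkeleton,
    NodeSpec,
    PhantomSpec,
    StemPath,
    VoxelVolume,
    branch_traits,
    detect_nodes_and_branches,
    generate_phantom,
    identify_stem,
    prepare_mask,
    remove_seeds,
    skeletonize_with_radius,
    write_swc,
)


def tube_mask(shape, p0, p1, radius):
    grid = np.moveaxis(np.mgrid[0:shape[0], 0:shape[1], 0:shape[2]], 0, -1).astype(float)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    d = p1 - p0
    t = np.clip(((grid - p0) @ d) / (d @ d), 0.0, 1.0)
    return ((grid - (p0 + t[..., None] * d)) ** 2).sum(-1) <= radius**2


class TestRemoveSeeds:
    def test_ground_truth_seed_removal_leaves_branch_only_volume(self, small_phantom):
        vol, truth = small_phantom
        seedless = remove_seeds(vol, (truth.label_map >= 10).astype(np.int32))
        assert (seedless.intensities[truth.label_map >= 10] == 0).all()
        untouched = truth.label_map < 10
        np.testing.assert_array_equal(seedless.intensities[untouched],
                                      vol.intensities[untouched])

    def test_removal_is_idempotent_and_no_labels_is_identity(self, small_phantom):
        vol, truth = small_phantom
        labels = (truth.label_map >= 10).astype(np.int32)
        once = remove_seeds(vol, labels)
        twice = remove_seeds(once, labels)
        np.testing.assert_array_equal(once.intensities, twice.intensities)
        same = remove_seeds(vol, np.zeros_like(labels))
        np.testing.assert_array_equal(same.intensities, vol.intensities)


class TestPrepareMask:
    def test_downsampled_dims_and_hole_filling(self):
        arr = np.zeros((41, 30, 30), dtype=np.float32)
        # hollow tube: wall at radius 6..9
        zz, yy, xx = np.mgrid[0:41, 0:30, 0:30]
        r2 = (yy - 15) ** 2 + (xx - 15) ** 2
        arr[(r2 <= 81) & (r2 >= 36) & (zz >= 2) & (zz < 39)] = 600.0
        mask, edge = prepare_mask(VoxelVolume(arr, 214.0), downsample=2)
        assert mask.shape == (21, 15, 15)  # ceil(original / 2)
        assert edge == 428.0
        # interior filled: mid-slice has no hole
        mid = mask[10]
        assert mid[7, 7]

    def test_filled_volume_not_smaller_than_thresholded(self):
        arr = np.zeros((20, 20, 20), dtype=np.float32)
        arr[4:16, 4:16, 4:16] = 600.0
        arr[8:12, 8:12, 8:12] = 0.0  # internal cavity
        mask, _ = prepare_mask(VoxelVolume(arr, 214.0), downsample=1)
        assert mask.sum() >= (arr > 300).sum()


class TestSkeletonize:
    def test_cylinder_axis_and_radius(self):
        mask = tube_mask((104, 16, 16), (2, 7.3, 7.6), (102, 7.3, 7.6), 5.0)
        sk = skeletonize_with_radius(mask, 1000.0)
        assert len(sk.vertices) < 0.05 * mask.sum()
        # single path: all degrees ≤ 2, two endpoints
        deg = Counter(dict(sk.graph.degree()).values())
        assert deg[1] == 2 and deg.get(3, 0) == 0
        assert np.abs(sk.vertices[:, 1:] - [7.3, 7.6]).max() <= 1.0
        assert sk.radii.mean() == pytest.approx(5.0, abs=0.7)

    def test_y_junction_count(self):
        t1 = tube_mask((60, 40, 30), (2, 20, 14.7), (30, 20, 14.7), 3.0)
        t2 = tube_mask((60, 40, 30), (30, 20, 14.7), (55, 35, 14.7), 3.4)
        t3 = tube_mask((60, 40, 30), (30, 20, 14.7), (55, 5, 14.7), 3.4)
        sk = skeletonize_with_radius(t1 | t2 | t3, 1000.0)
        deg = Counter(dict(sk.graph.degree()).values())
        assert deg[3] == 1 and deg[1] == 3

    def test_homotopy_loop_preserved(self):
        zz, yy, xx = np.mgrid[0:60, 0:40, 0:30]
        torus = ((np.sqrt((yy - 20.0) ** 2 + (xx - 14.0) ** 2) - 12) ** 2
                 + (zz - 30.0) ** 2) <= 16
        sk = skeletonize_with_radius(torus, 1000.0)
        loops = len(sk.edges) - len(sk.vertices) + nx.number_connected_components(sk.graph)
        assert loops == 1
        solid = tube_mask((60, 40, 30), (5, 20, 14.7), (55, 20, 14.7), 5.0)
        sk2 = skeletonize_with_radius(solid, 1000.0)
        loops2 = len(sk2.edges) - len(sk2.vertices) + nx.number_connected_components(sk2.graph)
        assert loops2 == 0


class TestIdentifyStem:
    @pytest.fixture(scope="class")
    def thick_stalk(self):
        spec = PhantomSpec(stalk_base_radius=6.0, stalk_tip_radius=6.0, height=150.0,
                           nodes=[NodeSpec(float(a), branch_length=30.0, angle=45.0)
                                  for a in np.linspace(30, 120, 6)],
                           seeds_per_branch=0, branch_radius=2.0, noise_sd=0.0,
                           voxel_edge=500.0, rng_seed=3)
        vol, truth = generate_phantom(spec)
        mask, edge = prepare_mask(vol, downsample=1)
        sk = skeletonize_with_radius(mask, edge)
        return sk, identify_stem(sk), truth

    def test_stem_lies_on_the_stalk_axis(self, thick_stalk):
        _, stem, truth = thick_stalk
        axis_yx = truth.stalk["base_point"][1:]
        assert np.abs(stem.polyline[:, 1:] - axis_yx).max() <= 1.5

    def test_stalk_diameter(self, thick_stalk):
        _, stem, _ = thick_stalk
        assert stem.main_stalk_diameter == pytest.approx(12.0, abs=1.5)

    def test_stem_length_close_to_stalk_height(self, thick_stalk):
        _, stem, truth = thick_stalk
        assert stem.length == pytest.approx(truth.stalk["height"], rel=0.05)

    def test_bottleneck_rule_prefers_the_wider_path(self):
        # hand-built skeleton: two parallel chains, min radii 6 vs 3
        pts, radii, edges = [], [], []
        for x, r in ((0.0, 6.0), (4.0, 3.0)):
            start = len(pts)
            for z in range(12):
                pts.append([float(z), 0.0, x])
                radii.append(r if 0 < z < 11 else 7.0)
            edges += [(start + i, start + i + 1) for i in range(11)]
        edges += [(0, 12), (11, 23)]  # join at both ends
        sk = CurveSkeleton(np.array(pts), np.array(radii), np.array(edges))
        stem = identify_stem(sk, high_percentile=80, low_percentile=10)
        xs = sk.vertices[stem.vertex_indices][:, 2]
        assert (xs[1:-1] == 0.0).all()


class TestBranches:
    def test_phantom_branch_count_and_node_positions(self, small_phantom_record):
        record, details, truth = small_phantom_record
        branches = details["branches"]
        assert len(branches) == truth.branch_count
        det_z = np.sort([b.node_point[0] for b in branches])
        gt_z = np.sort([b["node_z"] for b in truth.branches])
        # node positions within 2 working-resolution voxels
        assert np.abs(det_z - gt_z).max() <= 2 * 0.428

    def test_straight_continuation_preferred_at_junctions(self):
        """A short side twig must not hijack the branch tracing."""
        pts, radii = [], []
        for z in range(15):  # stem
            pts.append([float(z), 0.0, 0.0])
            radii.append(3.0)
        edges = [(i, i + 1) for i in range(14)]
        main_start = len(pts)
        for i in range(1, 13):  # branch at 45° in the y-plane from node z=5
            pts.append([5.0 + i * 0.7071, i * 0.7071, 0.0])
            radii.append(1.0)
        edges.append((5, main_start))
        edges += [(main_start + i, main_start + i + 1) for i in range(11)]
        twig_start = len(pts)
        for i in range(1, 4):  # sharp twig off the branch mid-point
            pts.append([5.0 + 6 * 0.7071 - i * 0.9, (6 + i) * 0.7071, 0.0])
            radii.append(1.0)
        edges.append((main_start + 5, twig_start))
        edges += [(twig_start + i, twig_start + i + 1) for i in range(2)]
        sk = CurveSkeleton(np.array(pts), np.array(radii), np.array(edges))
        stem = StemPath(list(range(15)), np.array(pts[:15]), 14.0, 6.0, 3.0)
        branches = detect_nodes_and_branches(sk, stem, min_branch_len=5.0,
                                             refine_nodes=False)
        assert len(branches) == 1
        tip = sk.vertices[branches[0].path[-1]]
        np.testing.assert_allclose(tip, [5.0 + 12 * 0.7071, 12 * 0.7071, 0.0])

    def test_short_stub_rejected(self):
        pts = [[float(z), 0.0, 0.0] for z in range(15)]
        radii = [3.0] * 15
        edges = [(i, i + 1) for i in range(14)]
        pts += [[7.0, 1.0, 0.0], [7.0, 2.0, 0.0]]  # 2 mm stub
        radii += [1.0, 1.0]
        edges += [(7, 15), (15, 16)]
        sk = CurveSkeleton(np.array(pts), np.array(radii), np.array(edges))
        stem = StemPath(list(range(15)), np.array(pts[:15]), 14.0, 6.0, 3.0)
        assert detect_nodes_and_branches(sk, stem, min_branch_len=5.0) == []


class TestBranchTraits:
    def _branch(self, node_arc, length=12.0, tip=45.0):
        return Branch(0, [0, 1], length, tip, node_arc, np.zeros(3))

    def test_internode_arithmetic(self):
        stem = StemPath([0, 1], np.array([[0.0, 0, 0], [100.0, 0, 0]]), 100.0, 8.0, 4.0)
        branches = [self._branch(a) for a in (10.0, 30.0, 70.0, 80.0)]
        out = branch_traits(branches, stem, panicle_depth=240.0)
        assert out["LongestInternodeLength"] == pytest.approx(40.0)
        assert out["SecondLongestInternodeLength"] == pytest.approx(20.0)
        assert out["FirstPrimaryBranchLength"] == pytest.approx(12.0)

    def test_branch_density(self):
        stem = StemPath([0, 1], np.array([[0.0, 0, 0], [100.0, 0, 0]]), 100.0, 8.0, 4.0)
        branches = [self._branch(10.0 + 5 * i) for i in range(12)]
        out = branch_traits(branches, stem, panicle_depth=240.0)
        assert out["PrimaryBranchNumberPerDepth"] == pytest.approx(0.05)

    def test_no_branches_gives_absent_traits(self):
        stem = StemPath([0, 1], np.array([[0.0, 0, 0], [100.0, 0, 0]]), 100.0, 8.0, 4.0)
        out = branch_traits([], stem, panicle_depth=100.0)
        assert out["PrimaryBranchNumber"] == 0
        assert np.isnan(out["LongestInternodeLength"])
        assert out["MainStalkDiameter"] == pytest.approx(8.0)


class TestSWC:
    def test_export_is_a_valid_tree(self, small_phantom_record, tmp_path):
        _, details, _ = small_phantom_record
        sk, stem, branches = details["skeleton"], details["stem"], details["branches"]
        path = tmp_path / "skeleton.swc"
        write_swc(sk, stem, branches, path)
        rows = [line.split() for line in path.read_text().splitlines()
                if not line.startswith("#")]
        assert len(rows) == len(sk.vertices)
        ids = {int(r[0]) for r in rows}
        parents = [int(r[6]) for r in rows]
        assert parents.count(-1) == 1
        assert all(p in ids for p in parents if p != -1)
        types = Counter(int(r[1]) for r in rows)
        assert types[1] == len(stem.vertex_indices)
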