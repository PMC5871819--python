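"""Radiomic descriptors: height filtration, directional complexity,
branch proximity, void barcodes, baselines and normalisation."""

import math

import numpy as np
import pytest

from airwaytopo import (
    AirwayTree,
    ScanMeta,
    branch_to_branch_proximity,
    directional_complexity,
    emphysema_score,
    height_function,
    lumen_volume,
    normalize_by_height,
    upwards_complexity,
    void_barcode,
    voxel_to_pointcloud,
    VoxelVolume,
)
from airwaytopo.errors import DegenerateInputError, MissingLabelsError
from airwaytopo.synthetic import (
    TreeGenParams,
    generate_airway_tree,
    generate_lung_phantom,
    hollow_sphere_volume,
    PhantomParams,
)
from conftest import random_graph_tree
from oracles import local_minima_count, plain_reduction


def _polyline(zs, x0=0.0):
    n = len(zs)
    return AirwayTree(
        ids=np.arange(1, n + 1),
        positions=[[x0 + 0.1 * k, 0.0, z] for k, z in enumerate(zs)],
        parent_ids=[-1] + list(range(1, n)),
    )


class TestHeightFunction:
    def test_topmost_zero_and_range(self):
        t = _polyline(np.linspace(0, -10, 11))
        f = height_function(t)
        vals = sorted(f.vertex_values.values())
        assert vals[0] == 0.0
        assert vals[-1] == pytest.approx(10.0)

    def test_invariant_under_horizontal_translation(self):
        t = _polyline([0, -3, -1, -5])
        t2 = AirwayTree(
            ids=t.ids,
            positions=t.positions + np.array([25.0, -13.0, 0.0]),
            parent_ids=t.parent_ids,
        )
        f1, f2 = height_function(t), height_function(t2)
        assert f1.vertex_values == f2.vertex_values


class TestDirectionalComplexity:
    def test_descending_path_zero(self):
        assert upwards_complexity(_polyline(np.linspace(0, -20, 30))) == 0

    def test_n_shaped_polyline_one_upward_excursion(self):
        zs = list(np.linspace(0, -10, 11)) + list(
            np.linspace(-9.5, -5, 5)
        ) + list(np.linspace(-5.5, -15, 10))
        assert upwards_complexity(_polyline(zs)) == 1

    def test_matches_local_minima_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            tree = random_graph_tree(rng, 80)
            depth = height_function(tree)
            vals = np.array([depth[int(i)] for i in tree.ids])
            edges = [tuple(e) for e in tree.edges()]
            expected = local_minima_count(vals, edges) - 1  # one component
            assert upwards_complexity(tree) == expected

    def test_angles_zero_equals_upwards(self, small_tree):
        tree, _ = small_tree
        assert directional_complexity(tree, (0, 0, 0)) == upwards_complexity(tree)

    def test_flip_counts_downward_turns(self):
        # N-shaped polyline: one upward excursion; flipped 180 degrees the
        # valley becomes the single upward turn.  Together the two counts
        # equal the number of interior trajectory extrema (apex + valley).
        zs = list(np.linspace(0, -10, 11)) + list(
            np.linspace(-9.5, -5, 5)
        ) + list(np.linspace(-5.5, -15, 10))
        t = _polyline(zs)
        up = upwards_complexity(t)
        down = directional_complexity(t, (180, 0, 0))
        assert up == 1 and down == 1
        assert up + down == 2  # interior extrema of depth along the path

    def test_invariant_under_rotation_about_vertical(self, small_tree):
        tree, _ = small_tree
        assert directional_complexity(tree, (0, 0, 77.5)) == upwards_complexity(tree)

    def test_degenerate_trees_return_zero(self):
        single = AirwayTree(ids=[1], positions=[[0, 0, 0]], parent_ids=[-1])
        assert upwards_complexity(single) == 0
        assert directional_complexity(single, (10, 20, 0)) == 0


class TestProximity:
    def test_straight_branch_zero(self):
        t = _polyline(np.linspace(0, -30, 50))
        t.positions[:, 0] = 0.0  # exactly collinear
        assert branch_to_branch_proximity(t) == 0.0

    def test_hairpin_positive(self):
        # two parallel 20-node arms 1 mm apart joined at the bottom
        zs = np.linspace(0, -19, 20)
        left = [[0.0, 0.0, z] for z in zs]
        right = [[1.0, 0.0, z] for z in zs[::-1]]
        pos = left + right
        t = AirwayTree(
            ids=np.arange(1, 41),
            positions=pos,
            parent_ids=[-1] + list(range(1, 40)),
        )
        assert branch_to_branch_proximity(t, jitter_seed=1) > 0

    def test_matches_reduction_oracle(self):
        rng = np.random.default_rng(8)
        tree = random_graph_tree(rng, 18)
        from airwaytopo import alpha_filtration

        cx = alpha_filtration(tree.positions, jitter_seed=5)
        deg1 = plain_reduction(cx.simplices).get(1, [])
        expected = sum(d - b for b, d in deg1 if math.isfinite(d))
        got = branch_to_branch_proximity(tree, jitter_seed=5)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_scales_linearly_with_coordinates(self):
        rng = np.random.default_rng(2)
        tree = random_graph_tree(rng, 30)
        big = AirwayTree(
            ids=tree.ids, positions=2.5 * tree.positions, parent_ids=tree.parent_ids
        )
        p1 = branch_to_branch_proximity(tree, jitter_seed=3)
        p2 = branch_to_branch_proximity(big, jitter_seed=3)
        assert p2 == pytest.approx(2.5 * p1, rel=1e-3)


class TestVoidBarcode:
    def test_hollow_sphere_dominant_void(self):
        vol = hollow_sphere_volume(radius_mm=10.0, spacing_mm=0.7)
        bc = void_barcode(vol, jitter_seed=0, max_points=600)
        dom = max(bc.bars, key=lambda bd: bd[1] - bd[0])
        assert abs(dom[1] - 10.0) < 0.5

    def test_solid_cube_no_large_void(self):
        grid = np.ones((6, 6, 6), dtype=np.uint8)
        vol = VoxelVolume(grid, (1.0, 1.0, 1.0), (0, 0, 0), "surface_labels")
        bc = void_barcode(vol, jitter_seed=0)
        if bc.bars:
            assert max(d - b for b, d in bc.bars) < 1.0  # below voxel spacing

    def test_identical_phantoms_distance_zero(self):
        from airwaytopo import bottleneck_distance

        vol = hollow_sphere_volume(radius_mm=6.0, spacing_mm=1.6)
        b1 = void_barcode(vol, jitter_seed=4)
        b2 = void_barcode(vol, jitter_seed=4)
        assert bottleneck_distance(b1, b2) == 0.0


class TestVoxelBaselines:
    def test_pointcloud_arithmetic(self):
        grid = np.zeros((3, 3, 3), dtype=np.uint8)
        grid[0, 0, 0] = 1
        grid[2, 1, 0] = 1
        vol = VoxelVolume(grid, (0.7, 0.7, 0.7), (0, 0, 0), "lumen_mask")
        pts = voxel_to_pointcloud(vol)
        assert np.allclose(sorted(pts.tolist()), [[0, 0, 0], [1.4, 0.7, 0]])

    def test_empty_grid_rejected(self):
        vol = VoxelVolume(np.zeros((2, 2, 2), dtype=np.uint8), kind="lumen_mask")
        with pytest.raises(DegenerateInputError):
            voxel_to_pointcloud(vol)

    @pytest.mark.parametrize(
        "n_low,expected", [(3, 30.0), (0, 0.0), (10, 100.0)]
    )
    def test_emphysema_fractions(self, n_low, expected):
        hu = np.full((10, 1, 1), -800, dtype=np.int16)
        hu[:n_low, 0, 0] = -980
        vol = VoxelVolume(hu, kind="hu_attenuation")
        mask = VoxelVolume(np.ones_like(hu, dtype=np.uint8), kind="lung_mask")
        assert emphysema_score(vol, mask, -950) == pytest.approx(expected)

    def test_empty_lung_mask_rejected(self):
        hu = VoxelVolume(np.zeros((2, 2, 2), dtype=np.int16), kind="hu_attenuation")
        mask = VoxelVolume(np.zeros((2, 2, 2), dtype=np.uint8), kind="lung_mask")
        with pytest.raises(ValueError):
            emphysema_score(hu, mask)

    def test_lumen_volume_counts(self):
        grid = np.zeros((5, 5, 5), dtype=np.uint8)
        grid.flat[:42] = 1
        assert lumen_volume(VoxelVolume(grid, kind="lumen_mask")) == 42
        assert lumen_volume(VoxelVolume(np.zeros((2, 2, 2), np.uint8), kind="lumen_mask")) == 0

    def test_nifti_round_trip(self, tmp_path):
        from airwaytopo import read_volume, write_volume

        rng = np.random.default_rng(1)
        grid = (rng.uniform(size=(8, 7, 6)) < 0.3).astype(np.uint8)
        vol = VoxelVolume(grid, (0.7, 0.7, 0.7), (-2.0, 1.0, 0.5), "lung_mask")
        p = tmp_path / "m.nii.gz"
        write_volume(vol, p)
        back = read_volume(p, "lung_mask")
        assert np.array_equal(back.grid, vol.grid)
        assert back.spacing == pytest.approx(vol.spacing)
        assert back.origin == pytest.approx(vol.origin)

    def test_phantom_ground_truth(self):
        vols, truth = generate_lung_phantom(
            PhantomParams(voxel_spacing_mm=1.5, emphysema_fraction=0.30, seed=3)
        )
        assert lumen_volume(vols["lumen_mask"]) == truth["lumen_voxels"]
        score = emphysema_score(vols["hu"], vols["lung_mask"], -950)
        assert score == pytest.approx(30.0, abs=0.5)
        assert score == pytest.approx(100 * truth["emphysema_fraction_actual"], abs=1e-9)


class TestNormalization:
    def test_per_metre(self):
        meta = ScanMeta("P1", "HNS", "inspiratory", 1.80)
        assert normalize_by_height(100, meta) == pytest.approx(55.56, abs=0.01)

    def test_missing_height_rejected(self):
        meta = ScanMeta("P1", "HNS", "inspiratory", None)
        with pytest.raises(MissingLabelsError):
            normalize_by_height(100, meta)
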