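import numpy as np
import pytest

from earmorph.morphometry import (
    MorphometryResult,
    cartilage_surface,
    cartilage_volume,
    mean_thickness,
    morphometry_all,
    thickness_map,
)
from earmorph.volume_io import VoxelGrid

from conftest import box_grid, shell_grid, sphere_grid


def brute_force_thickness(mask: np.ndarray, h: float) -> np.ndarray:
    """Independent per-voxel evaluation of the maximal-covering-sphere rule.

    Uses the same candidate-sphere construction as the implementation
    (voxel centres plus face midpoints, radius = surface distance) but
    evaluates the covering maximum directly per voxel instead of via the
    level-by-level EDT passes, so it checks the covering algorithm.
    """
    from scipy import ndimage

    mask = np.asarray(mask, bool)
    d = ndimage.distance_transform_edt(mask, sampling=h)
    r = np.where(mask, d - h / 2.0, -1e6)
    v = np.where(mask, 2.0 * r, 0.0)
    for ax in range(3):
        r2 = np.roll(r, -1, axis=ax)
        r0 = np.roll(r, 1, axis=ax)
        r3 = np.roll(r, -2, axis=ax)
        s1 = np.clip((r - r0) / h, 0.0, 1.0)
        s2 = np.clip((r2 - r3) / h, 0.0, 1.0)
        both = (s1 > 0) & (s2 > 0)
        denom = np.where(both, s1 + s2, 1.0)
        peak = np.where(both, (s2 * r + s1 * r2 + s1 * s2 * h) / denom, -1e6)
        mid = np.maximum(peak, np.maximum(r, r2))
        ok = mask & np.roll(mask, -1, axis=ax)
        cand = np.where(ok, 2.0 * mid, 0.0)
        v = np.maximum(v, cand)
        v = np.maximum(v, np.roll(cand, 1, axis=ax))
    centers = np.argwhere(v > 0)
    vals = v[v > 0]
    out = np.zeros(mask.shape)
    for p in np.argwhere(mask):
        dist = np.linalg.norm((centers - p) * h, axis=1)
        cov = dist <= vals / 2.0 + 1e-9
        out[tuple(p)] = vals[cov].max() if cov.any() else max(v[tuple(p)], h)
    out[mask] = np.maximum(out[mask], h)
    return out


class TestVolume:
    def test_empty_mask_is_zero(self):
        g = VoxelGrid(np.zeros((5, 5, 5), bool), (1, 1, 1))
        assert cartilage_volume(g) == 0.0

    def test_full_cube_counting(self):
        g = VoxelGrid(np.ones((10, 10, 10), bool), (1, 1, 1))
        assert cartilage_volume(g) == pytest.approx(1000.0)

    def test_sphere_against_closed_form(self, sphere_r5_h01):
        true = 4.0 / 3.0 * np.pi * 5.0**3
        assert cartilage_volume(sphere_r5_h01) == pytest.approx(true, rel=0.01)

    def test_anisotropic_voxel_volume_used(self):
        g = VoxelGrid(np.ones((10, 10, 10), bool), (0.45, 0.45, 0.40))
        assert cartilage_volume(g) == pytest.approx(1000 * 0.45 * 0.45 * 0.40)


class TestSurface:
    def test_empty_mask_is_zero(self):
        g = VoxelGrid(np.zeros((5, 5, 5), bool), (1, 1, 1))
        assert cartilage_surface(g) == 0.0

    def test_sphere_against_closed_form(self, sphere_r5_h01):
        true = 4.0 * np.pi * 5.0**2
        assert cartilage_surface(sphere_r5_h01) == pytest.approx(true, rel=0.02)

    def test_box_against_closed_form(self):
        g = box_grid((20.0, 20.0, 5.0), 0.1)
        true = 2 * (20 * 20 + 20 * 5 + 5 * 20)
        assert cartilage_surface(g) == pytest.approx(true, rel=0.03)


class TestThickness:
    def test_empty_mask_raises(self):
        g = VoxelGrid(np.zeros((5, 5, 5), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="no foreground"):
            thickness_map(g)

    def test_slab_interior_and_max(self):
        g = box_grid((30.0, 30.0, 1.2), 0.1)
        tm = thickness_map(g)
        vals = tm.foreground_values
        assert vals.max() <= 1.2 + 2 * 0.1
        nz, ny, nx = g.data.shape
        assert tm.values[nz // 2, ny // 2, nx // 2] == pytest.approx(1.2, abs=0.02)
        assert mean_thickness(tm) == pytest.approx(1.2, abs=0.05)

    def test_shell_wall_thickness(self, shell_8_1_h01):
        tm = thickness_map(shell_8_1_h01)
        vals = tm.foreground_values
        assert vals.min() >= 0.9
        assert vals.max() <= 1.1

    def test_single_voxel_inscribed_sphere(self):
        data = np.zeros((7, 7, 7), bool)
        data[3, 3, 3] = True
        tm = thickness_map(VoxelGrid(data, (1, 1, 1)))
        assert tm.values[3, 3, 3] == pytest.approx(1.0)

    def test_two_region_sheet_mean(self):
        # equal volumes at thickness 1.0 and 2.0 -> volume-weighted mean 1.5
        h = 0.1
        data = np.zeros((26, 106, 306), bool)
        data[3:13, 3:103, 3:203] = True  # 20 x 10 mm at 1.0 mm
        data[3:23, 3:103, 203:303] = True  # 10 x 10 mm at 2.0 mm
        tm = thickness_map(VoxelGrid(data, (h, h, h)))
        assert mean_thickness(tm) == pytest.approx(1.5, abs=0.05)

    def test_matches_brute_force_on_random_blob(self):
        rs = np.random.default_rng(3)
        data = np.zeros((12, 12, 12), bool)
        data[3:9, 3:9, 3:9] = rs.random((6, 6, 6)) > 0.3
        tm = thickness_map(VoxelGrid(data, (0.5, 0.5, 0.5)), max_levels=10**9, tail_fraction=0.0)
        brute = brute_force_thickness(data, 0.5)
        np.testing.assert_allclose(tm.values, brute, atol=1e-9)

    def test_matches_brute_force_on_cube(self):
        # corners of a cube are covered only by small spheres, so the mean
        # is well below the edge length; the brute-force rule is the oracle
        data = np.zeros((14, 14, 14), bool)
        data[2:12, 2:12, 2:12] = True
        tm = thickness_map(VoxelGrid(data, (1.0, 1.0, 1.0)), max_levels=10**9, tail_fraction=0.0)
        brute = brute_force_thickness(data, 1.0)
        np.testing.assert_allclose(tm.values, brute, atol=1e-9)
        assert mean_thickness(tm) < 10.0


class TestMorphometryAll:
    def test_empty_mask_all_zero(self):
        g = VoxelGrid(np.zeros((4, 4, 4), bool), (1, 1, 1))
        res = morphometry_all(g, "empty")
        assert (res.cg_v, res.cg_s, res.cg_th) == (0.0, 0.0, 0.0)

    def test_shell_phantom_closed_forms(self, shell_8_1_h01):
        res = morphometry_all(shell_8_1_h01, "shell")
        assert res.cg_v == pytest.approx(908.92, rel=0.01)
        assert res.cg_s == pytest.approx(1822.12, rel=0.03)
        assert res.cg_th == pytest.approx(1.0, rel=0.05)

    def test_cube_volume(self):
        g = box_grid((10.0, 10.0, 10.0), 0.2)
        assert cartilage_volume(g) == pytest.approx(1000.0, rel=0.01)

    def test_mean_thickness_consistency(self):
        g = box_grid((8.0, 8.0, 1.0), 0.2)
        res = morphometry_all(g, "slab")
        assert res.cg_th == mean_thickness(thickness_map(g))

    def test_result_invariants(self):
        with pytest.raises(ValueError):
            MorphometryResult("bad", -1.0, 0.0, 0.0, (1, 1, 1))


class TestProperties:
    def test_volume_monotone_under_inclusion(self):
        rs = np.random.default_rng(7)
        a = rs.random((8, 8, 8)) > 0.6
        b = a | (rs.random((8, 8, 8)) > 0.8)
        ga = VoxelGrid(a, (0.3, 0.3, 0.3))
        gb = VoxelGrid(b, (0.3, 0.3, 0.3))
        assert cartilage_volume(ga) <= cartilage_volume(gb)

    def test_translation_invariance(self):
        g = box_grid((2.0, 1.5, 1.0), 0.25, pad=6)
        shifted = VoxelGrid(np.roll(g.data, (2, -1, 3), axis=(0, 1, 2)), g.spacing)
        r0 = morphometry_all(g)
        r1 = morphometry_all(shifted)
        assert r1.cg_v == pytest.approx(r0.cg_v)
        assert r1.cg_s == pytest.approx(r0.cg_s, rel=1e-6)
        assert r1.cg_th == pytest.approx(r0.cg_th, rel=1e-9)

    def test_resolution_consistency_on_shell(self):
        coarse = morphometry_all(shell_grid(4.0, 1.0, 0.2), "c")
        fine = morphometry_all(shell_grid(4.0, 1.0, 0.1), "f")
        assert coarse.cg_v == pytest.approx(fine.cg_v, rel=0.03)
        assert coarse.cg_s == pytest.approx(fine.cg_s, rel=0.03)
        assert coarse.cg_th == pytest.approx(fine.cg_th, abs=0.2)

    def test_slab_layer_structure_relation(self):
        # V / ((S/2) * Th) -> 1 as the lateral/thickness ratio grows
        g = box_grid((40.0, 40.0, 1.0), 0.2)
        res = morphometry_all(g)
        ratio = res.cg_v / ((res.cg_s / 2.0) * res.cg_th)
        assert ratio == pytest.approx(1.0, abs=0.05)
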