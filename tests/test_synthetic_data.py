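import numpy as np
import pytest

from earmorph.morphometry import cartilage_volume, mean_thickness, thickness_map
from earmorph.synthetic_data import (
    PhantomSpec,
    PopulationSpec,
    RaterModel,
    default_raters,
    emulate_ct,
    make_phantom,
    simulate_population,
    simulate_rater,
)


class TestPhantomSpec:
    def test_slab_truth_closed_forms(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(30.0, 30.0))
        t = spec.truth()
        assert t["cg_v"] == pytest.approx(30 * 30 * 1.2)  # 1080 exactly
        assert t["cg_s"] == pytest.approx(2 * 900 + 2 * 1.2 * 60)
        assert t["cg_th"] == 1.2
        assert not t["numerical"]

    def test_shell_truth_closed_forms(self):
        spec = PhantomSpec(shape="spherical_shell", thickness=1.0, inner_radius=8.0)
        t = spec.truth()
        assert t["cg_v"] == pytest.approx(4 / 3 * np.pi * (9**3 - 8**3))  # 908.92
        assert t["cg_s"] == pytest.approx(4 * np.pi * (8**2 + 9**2))  # 1822.12
        assert t["cg_th"] == 1.0

    def test_bent_sheet_truth_is_numerical_and_consistent(self):
        spec = PhantomSpec(shape="bent_sheet", thickness=1.15)
        t = spec.truth()
        assert t["numerical"]
        # unmodulated bent sheet has exact V = R * t * arc * L
        v_exact = spec.bend_radius * 1.15 * spec.arc_angle * spec.axial_length
        assert t["cg_v"] == pytest.approx(v_exact, rel=1e-3)
        assert t["cg_th"] == pytest.approx(1.15, rel=1e-6)

    def test_slab_layer_structure_limit_analytic(self):
        # V / ((S/2) Th) -> 1 as lateral extent grows, on truth values alone
        ratios = []
        for ext in (10.0, 40.0, 160.0):
            t = PhantomSpec(shape="slab", thickness=1.0, lateral_extent=(ext, ext)).truth()
            ratios.append(t["cg_v"] / ((t["cg_s"] / 2) * t["cg_th"]))
        assert ratios[0] < ratios[1] < ratios[2] < 1.0
        assert ratios[2] == pytest.approx(1.0, abs=0.02)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(shape="slab", thickness=0.0)
        with pytest.raises(ValueError):
            PhantomSpec(shape="slab", thickness=1.0, thickness_modulation=(0.6, 5.0))


class TestMakePhantom:
    def test_slab_rasterization_matches_truth(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(30.0, 30.0))
        grid, truth = make_phantom(spec, (0.1, 0.1, 0.1))
        assert cartilage_volume(grid) == pytest.approx(truth["cg_v"], rel=0.01)

    def test_too_coarse_spacing_rejected(self):
        spec = PhantomSpec(shape="slab", thickness=0.2)
        with pytest.raises(ValueError, match="spacing too coarse"):
            make_phantom(spec, (0.45, 0.45, 0.45))

    def test_marginal_spacing_warns(self):
        spec = PhantomSpec(shape="slab", thickness=1.15, lateral_extent=(10.0, 10.0))
        with pytest.warns(UserWarning, match="voxels across"):
            make_phantom(spec, (0.45, 0.45, 0.40))


class TestSimulateRater:
    def test_null_rater_is_identity(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(10.0, 10.0))
        grid, _ = make_phantom(spec, (0.1, 0.1, 0.1))
        out = simulate_rater(spec, RaterModel(bias=0.0, noise_amplitude=0.0),
                             (0.1, 0.1, 0.1))
        np.testing.assert_array_equal(out.data, grid.data)

    def test_positive_bias_thickens_slab(self):
        # +1 voxel bias moves each face out one voxel: Th grows by 2h = 0.2
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(15.0, 15.0))
        h = 0.1
        base, _ = make_phantom(spec, (h, h, h))
        out = simulate_rater(spec, RaterModel(bias=1.0, noise_amplitude=0.0), (h, h, h))
        th0 = mean_thickness(thickness_map(base))
        th1 = mean_thickness(thickness_map(out))
        assert th1 - th0 == pytest.approx(0.2, abs=0.03)

    def test_determinism_same_seed(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(10.0, 10.0))
        m = RaterModel(noise_amplitude=0.5, seed=77)
        a = simulate_rater(spec, m, (0.15, 0.15, 0.15))
        b = simulate_rater(spec, m, (0.15, 0.15, 0.15))
        np.testing.assert_array_equal(a.data, b.data)

    def test_amplitude_orders_thickness_spread(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(15.0, 15.0))
        h = 0.15
        spreads = []
        for amp in (0.25, 0.5):
            ths = []
            for seed in range(10):
                g = simulate_rater(
                    spec, RaterModel(noise_amplitude=amp, seed=seed), (h, h, h)
                )
                ths.append(mean_thickness(thickness_map(g)))
            spreads.append(np.std(ths))
        assert spreads[0] < spreads[1]

    def test_zero_bias_noise_leaves_volume_unbiased(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(15.0, 15.0))
        h = 0.15
        base, truth = make_phantom(spec, (h, h, h))
        v0 = cartilage_volume(base)
        vols = [
            cartilage_volume(
                simulate_rater(spec, RaterModel(noise_amplitude=0.5, seed=s), (h, h, h))
            )
            for s in range(12)
        ]
        assert np.mean(vols) == pytest.approx(v0, rel=0.01)

    def test_accepts_voxel_grid_input(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(10.0, 10.0))
        grid, _ = make_phantom(spec, (0.1, 0.1, 0.1))
        out = simulate_rater(grid, RaterModel(bias=0.0, noise_amplitude=0.0))
        np.testing.assert_array_equal(out.data, grid.data)


class TestSimulatePopulation:
    def test_design_shape_14x3(self):
        pop = PopulationSpec(n_subjects=14, seed=1)
        study = simulate_population(pop, default_raters(3))
        n_masks = sum(len(v) for v in study.masks.values())
        assert n_masks == 42
        assert len(study.manifest) == 42
        assert len(study.truth) == 14

    def test_determinism(self):
        pop = PopulationSpec(n_subjects=2, seed=9)
        s1 = simulate_population(pop, default_raters(2))
        s2 = simulate_population(pop, default_raters(2))
        for sid in s1.masks:
            for rid in s1.masks[sid]:
                np.testing.assert_array_equal(
                    s1.masks[sid][rid].data, s2.masks[sid][rid].data
                )

    def test_empty_rater_list_rejected(self):
        with pytest.raises(ValueError, match="rater list"):
            simulate_population(PopulationSpec(n_subjects=2), [])


class TestEmulateCt:
    def test_interior_value_matches_attenuation(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(10.0, 10.0))
        vol = emulate_ct(spec, 0.1, cartilage_atten=1.5, background_atten=0.2,
                         noise_sd=0.02, seed=3)
        grid, _ = make_phantom(spec, (0.1, 0.1, 0.1))
        from scipy import ndimage

        interior = ndimage.binary_erosion(grid.data, iterations=2)
        inner_vals = vol.data[interior]
        assert inner_vals.mean() == pytest.approx(
            1.5, abs=3 * 0.02 / np.sqrt(interior.sum())
        )

    def test_determinism(self):
        spec = PhantomSpec(shape="slab", thickness=1.2, lateral_extent=(8.0, 8.0))
        v1 = emulate_ct(spec, 0.1, seed=5)
        v2 = emulate_ct(spec, 0.1, seed=5)
        np.testing.assert_array_equal(v1.data, v2.data)

    def test_implausible_attenuation_rejected(self):
        spec = PhantomSpec(shape="slab", thickness=1.2)
        with pytest.raises(ValueError, match="cartilage_atten"):
            emulate_ct(spec, 0.1, cartilage_atten=9.0)
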