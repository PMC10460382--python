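"""Synthetic-scene generator: sampling, placement, rendering physics."""

import numpy as np
import pytest

from gcwmorph import (
    ChannelSpec,
    Direction,
    Modality,
    ParameterError,
    PlacementError,
    VoxelGeometry,
    apply_axial_elongation_and_noise,
    build_scene,
    render_ef_channel,
    render_shg_channel,
    sample_granule_population,
    simulate_stack,
)
from gcwmorph.morphometry import histogram_modes
from gcwmorph.simulate import (
    SimulationParams,
    WallGeometry,
    _ellipsoid_indices,
    params_from_dict,
    params_to_dict,
)

from conftest import STRING_WALL, make_sim_params


class TestSimulationParams:
    def test_weights_must_sum_to_one(self):
        with pytest.raises(ParameterError):
            make_sim_params(mixture=((4, 0.1, 0.5), (6, 0.1, 0.4)))

    def test_malformed_mixture_names_field(self):
        with pytest.raises(ParameterError, match="mixture"):
            make_sim_params(mixture=((4, 0.1),))

    def test_attenuation_ordering_enforced(self):
        with pytest.raises(ParameterError):
            make_sim_params(atten_length_shg_um=50.0, atten_length_ef_um=40.0)

    def test_round_trip_dict(self):
        p = make_sim_params(seed=9)
        assert params_from_dict(params_to_dict(p)) == p


class TestSampleGranulePopulation:
    def test_n_zero_gives_empty_list(self):
        assert sample_granule_population(make_sim_params(), 0) == []

    def test_degenerate_mixture_is_monodisperse(self):
        p = make_sim_params(mixture=((6.0, 0.0, 1.0),))
        pop = sample_granule_population(p, 100)
        assert len(pop) == 100
        assert all(g.true_diameter_um == pytest.approx(6.0) for g in pop)
        assert all(g.size_class == "B" for g in pop)

    def test_trimodal_histogram_has_three_modes(self):
        pop = sample_granule_population(make_sim_params(seed=7), 5000)
        d = np.array([g.true_diameter_um for g in pop])
        modes = histogram_modes(d)
        by_class = {
            "C": [m for m in modes if m < 5],
            "B": [m for m in modes if 5 <= m <= 15],
            "A": [m for m in modes if m > 15],
        }
        assert all(len(v) == 1 for v in by_class.values()), modes
        assert by_class["C"][0] == pytest.approx(4.0, abs=1.0)
        assert by_class["B"][0] == pytest.approx(6.0, abs=1.0)
        assert by_class["A"][0] == pytest.approx(22.0, abs=2.0)

    def test_a_type_is_oblate_lenticular(self):
        pop = sample_granule_population(make_sim_params(seed=11), 400)
        for g in pop:
            a, b, c = g.semi_axes_um
            if g.size_class == "A":
                assert c == pytest.approx(0.4 * a)
            else:
                assert 0.85 * a <= min(b, c) <= a + 1e-9

    def test_deterministic_given_seed(self):
        p = make_sim_params(seed=5)
        assert sample_granule_population(p, 50) == sample_granule_population(p, 50)


class TestBuildScene:
    def test_target_zero_gives_gluten_only_wall(self):
        scene = build_scene(make_sim_params(target_starch_fraction=0.0), STRING_WALL)
        assert scene.granules == []
        assert not scene.granule_mask.any()
        assert scene.wall_mask.any()

    def test_achieved_fraction_within_tolerance_and_exact_record(self):
        scene = build_scene(make_sim_params(target_starch_fraction=0.55), STRING_WALL)
        assert scene.achieved_fraction == pytest.approx(0.55, abs=0.02)
        # recorded value must equal the direct voxel count
        zs = list(scene.central_slices)
        direct = (scene.granule_labels[zs] > 0).sum() / scene.wall_mask[zs].sum()
        assert scene.achieved_fraction == pytest.approx(direct, rel=1e-9)

    def test_granules_confined_to_wall(self):
        scene = build_scene(make_sim_params(target_starch_fraction=0.45), STRING_WALL)
        assert not (scene.granule_mask & ~scene.wall_mask).any()

    def test_overlap_under_one_percent_of_stack(self):
        scene = build_scene(make_sim_params(target_starch_fraction=0.65), STRING_WALL)
        claimed = np.zeros(scene.shape, np.int16)
        for g in scene.granules:
            idx = _ellipsoid_indices(
                g.center_um, g.semi_axes_um, g.orientation_rad,
                scene.shape, scene.geometry,
            )
            claimed[idx] += 1
        overlap_voxels = int((claimed > 1).sum())
        assert overlap_voxels < 0.01 * claimed.size

    def test_unachievable_fraction_raises_placement_error(self):
        # a sliver of a wall cannot hold 65% starch
        wall = WallGeometry("bulk", 6.0, 2.0, 2.0, z_offset_um=10.0)
        p = make_sim_params(target_starch_fraction=0.65, seed=4)
        with pytest.raises(PlacementError):
            build_scene(p, wall, max_batches=2)


class TestWallGeometry:
    def test_string_invariants_against_stack(self):
        wall = WallGeometry("string", 30, 10, 20, z_offset_um=0)
        with pytest.raises(Exception):
            wall.validate_against_stack(24.0)  # too deep for a string

    def test_intact_must_span_stack(self):
        wall = WallGeometry("intact", 30, 20, 10, z_offset_um=0)
        with pytest.raises(Exception):
            wall.validate_against_stack(24.0)


@pytest.fixture(scope="module")
def lone_granule_scene():
    p = make_sim_params(
        shape=(24, 128, 128), target_starch_fraction=0.0, seed=3,
        noise_scale=0.0,
    )
    wall = WallGeometry("bulk", 18.0, 16.0, 10.0, z_offset_um=1.0)
    scene = build_scene(p, wall)
    from conftest import place_granule

    place_granule(scene, (10.88, 10.88, 6.0), (4.0, 4.0, 3.0), 0.0)
    return scene


class TestRenderSHG:
    def test_ef_spec_rejected(self, lone_granule_scene):
        with pytest.raises(ParameterError):
            render_shg_channel(lone_granule_scene, ChannelSpec(Modality.EF))

    def test_two_lobe_ratio_at_least_four(self, lone_granule_scene):
        # polarization 0 deg: lobes on the x axis, nulls on the y axis
        field = render_shg_channel(
            lone_granule_scene, ChannelSpec(Modality.SHG, Direction.BACKWARD, 0)
        )
        geo = lone_granule_scene.geometry
        cx = cy = int(10.88 / geo.pixel_size_xy)
        cz = int(6.0 / geo.z_step)
        r = int(3.0 / geo.pixel_size_xy)
        on_lobe = max(field[cz, cy, cx + r], field[cz, cy, cx - r])
        off_lobe = max(field[cz, cy + r, cx], field[cz, cy - r, cx])
        assert on_lobe >= 4 * max(off_lobe, 1e-12)

    def test_hilum_is_exactly_zero(self, lone_granule_scene):
        field = render_shg_channel(
            lone_granule_scene, ChannelSpec(Modality.SHG, Direction.BACKWARD, 0)
        )
        geo = lone_granule_scene.geometry
        cx = cy = int(10.88 / geo.pixel_size_xy)
        cz = int(6.0 / geo.z_step)
        assert field[cz, cy, cx] == 0.0

    def test_backward_peripheral_forward_interior(self, lone_granule_scene):
        back = sum(
            render_shg_channel(
                lone_granule_scene, ChannelSpec(Modality.SHG, Direction.BACKWARD, a)
            )
            for a in (0, 45, 90, 135)
        )
        fwd = sum(
            render_shg_channel(
                lone_granule_scene, ChannelSpec(Modality.SHG, Direction.FORWARD, a)
            )
            for a in (0, 45, 90, 135)
        )
        g = lone_granule_scene.granules[0]
        geo = lone_granule_scene.geometry
        zz, yy, xx = np.nonzero(lone_granule_scene.granule_mask)
        dx = (xx + 0.5) * geo.pixel_size_xy - g.center_um[0]
        dy = (yy + 0.5) * geo.pixel_size_xy - g.center_um[1]
        dz = (zz + 0.5) * geo.z_step - g.center_um[2]
        rho = np.sqrt(
            (dx / g.semi_axes_um[0]) ** 2
            + (dy / g.semi_axes_um[1]) ** 2
            + (dz / g.semi_axes_um[2]) ** 2
        )
        periphery = rho > 0.8
        interior = (rho > 0.3) & (rho < 0.6)
        bvals, fvals = back[zz, yy, xx], fwd[zz, yy, xx]
        assert bvals[periphery].mean() > fvals[periphery].mean()
        assert fvals[interior].mean() > bvals[interior].mean()

    def test_attenuation_factor_non_increasing(self, lone_granule_scene):
        import dataclasses

        field = render_shg_channel(
            lone_granule_scene, ChannelSpec(Modality.SHG, Direction.BACKWARD, 0)
        )
        flat_params = dataclasses.replace(
            lone_granule_scene.params, atten_length_shg_um=1e9, atten_length_ef_um=2e9
        )
        flat_scene = dataclasses.replace(lone_granule_scene, params=flat_params)
        flat = render_shg_channel(
            flat_scene, ChannelSpec(Modality.SHG, Direction.BACKWARD, 0)
        )
        m = flat.sum(axis=(1, 2)) > 0
        ratio = field.sum(axis=(1, 2))[m] / flat.sum(axis=(1, 2))[m]
        assert (np.diff(ratio) <= 1e-9).all()


class TestRenderEF:
    def test_gas_is_dark_and_contrast_ratio(self, string_result):
        scene = string_result.scene
        field = render_ef_channel(scene, rng=np.random.default_rng(0))
        assert field[~scene.wall_mask].max() == 0.0
        # contrast at the top of the wall (before attenuation matters)
        zs = list(scene.central_slices)
        gluten = field[zs][scene.gluten_mask[zs]]
        interior = field[zs][scene.granule_mask[zs]]
        assert gluten.mean() / interior.mean() >= 3.0


class TestAxialElongationAndNoise:
    def test_factor_below_one_rejected(self):
        with pytest.raises(ParameterError):
            make_sim_params(z_elongation_factor=0.5)

    def test_identity_up_to_blur_normalization(self):
        p = make_sim_params(z_elongation_factor=1.0, noise_scale=0.0,
                            shape=(16, 32, 32))
        rng = np.random.default_rng(0)
        field = rng.uniform(0, 1, (16, 32, 32)).astype(np.float32)
        out = apply_axial_elongation_and_noise(field, p)
        assert out.sum() == pytest.approx(field.sum(), rel=1e-3)  # mass preserved

    def test_deterministic_given_seed(self):
        p = make_sim_params(shape=(12, 24, 24))
        field = np.random.default_rng(1).uniform(0, 10, (12, 24, 24)).astype(np.float32)
        a = apply_axial_elongation_and_noise(field, p, np.random.default_rng(42))
        b = apply_axial_elongation_and_noise(field, p, np.random.default_rng(42))
        assert np.array_equal(a, b)

    def test_half_max_aspect_grows_with_elongation_factor(self):
        # 10 µm sphere under an (exaggerated) 2.5 µm PSF; the half-max
        # z/xy aspect must grow monotonically with the factor and sit in the
        # band measured for this blur model at factor 2
        geo = VoxelGeometry()
        nz, n = 64, 128
        Z, Y, X = np.ogrid[:nz, :n, :n]
        r2 = (
            ((X - n // 2) * geo.pixel_size_xy) ** 2
            + ((Y - n // 2) * geo.pixel_size_xy) ** 2
            + ((Z - nz // 2) * geo.z_step) ** 2
        )
        sphere = (r2 <= 5.0**2).astype(np.float32)

        def aspect(factor):
            p = make_sim_params(
                shape=(nz, n, n), psf_sigma_um=2.5,
                z_elongation_factor=factor, noise_scale=0.0,
            )
            blurred = apply_axial_elongation_and_noise(sphere, p)
            iso = blurred >= blurred.max() / 2
            zext = np.flatnonzero(iso.any(axis=(1, 2)))
            xext = np.flatnonzero(iso.any(axis=(0, 1)))
            z_um = (zext[-1] - zext[0] + 1) * geo.z_step
            x_um = (xext[-1] - xext[0] + 1) * geo.pixel_size_xy
            return z_um / x_um

        a1, a2, a3 = aspect(1.0), aspect(2.0), aspect(3.0)
        assert a1 < a2 < a3
        assert 1.3 <= a2 <= 1.75


class TestSimulateStack:
    def test_nine_channels_shared_geometry(self, string_result):
        stack = string_result.stack
        assert stack.n_channels == 9
        assert stack.voxels.shape[0] == 9
        assert stack.voxels.dtype == np.uint16

    def test_byte_identical_given_seed(self):
        p = make_sim_params(shape=(24, 96, 96), target_starch_fraction=0.35, seed=8)
        wall = WallGeometry("string", 12.0, 6.0, 5.0, z_offset_um=3.0)
        a = simulate_stack(p, wall)
        b = simulate_stack(p, wall)
        assert a.stack.voxels.tobytes() == b.stack.voxels.tobytes()
        assert a.achieved_fraction == b.achieved_fraction

    def test_truth_count_matches_sidecar(self, string_result, tmp_path):
        paths = string_result.save(tmp_path)
        import json

        import pandas as pd

        truth = json.load(open(paths["truth"]))
        table = pd.read_csv(paths["truth_granules"])
        assert truth["n_granules"] == len(string_result.granules) == len(table)
        assert truth["achieved_starch_fraction"] == pytest.approx(
            string_result.achieved_fraction
        )
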