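"""Synthetic generator: speckle statistics, geometry, deformation truth,
rendering and study simulation."""

import numpy as np
import pytest
from skimage.registration import phase_cross_correlation

import stamps3d.synthetic as syn
from stamps3d import (
    Bump,
    CameraModel,
    SpeckleSpec,
    StudyDesign,
    coverage_fraction,
    default_effect_profile,
    make_deformation,
    make_insole_surface,
    make_speckle_texture,
    render_stereo_pair,
    rigid_translation_deformation,
    simulate_study,
)
from stamps3d.errors import (
    BumpOutsideInsole,
    InfeasibleSpeckleSpec,
    InvalidEffectProfile,
    InvalidGeometry,
)


class TestSpeckle:
    @pytest.mark.parametrize("density,lo,hi", [
        (0.65, 0.60, 0.70),   # nominal commercial-generator spec
        (0.001, 0.0, 0.01),   # vanishing density -> near-white image
    ])
    def test_measured_density_matches_spec(self, density, lo, hi):
        spec = SpeckleSpec(dot_density=density, seed=1)
        img = make_speckle_texture(spec, (512, 512))
        assert img.dtype == np.uint8
        assert lo <= coverage_fraction(img) <= hi

    def test_density_converges_with_size(self):
        spec = SpeckleSpec(seed=4)
        img = make_speckle_texture(spec, (2048, 2048))
        assert abs(coverage_fraction(img) - spec.dot_density) < 0.02

    def test_deterministic_under_seed(self):
        spec = SpeckleSpec(seed=9)
        a = make_speckle_texture(spec, (128, 128))
        b = make_speckle_texture(spec, (128, 128))
        np.testing.assert_array_equal(a, b)

    def test_polarity_configurable(self):
        dark = make_speckle_texture(SpeckleSpec(seed=2), (128, 128))
        light = make_speckle_texture(SpeckleSpec(seed=2, dark_on_light=False),
                                     (128, 128))
        np.testing.assert_array_equal(dark, 255 - light)

    @pytest.mark.parametrize("kwargs", [
        {"dot_density": 1.2}, {"dot_density": 1.0}, {"dot_diameter_mm": -1.0},
        {"diameter_variation": 1.0}, {"mm_per_px": 0.0},
    ])
    def test_infeasible_specs_rejected(self, kwargs):
        with pytest.raises(InfeasibleSpeckleSpec):
            SpeckleSpec(**kwargs)


class TestInsoleSurface:
    def test_flat_surface_has_zero_height(self, flat_surface):
        assert np.max(np.abs(flat_surface.grid_points[:, 2])) == 0.0

    def test_contoured_max_height_equals_arch(self, contoured_surface):
        zmax = contoured_surface.grid_points[:, 2].max()
        assert zmax == pytest.approx(12.0, abs=0.5)  # within grid resolution
        assert contoured_surface.grid_points[:, 2].min() > -1e-6

    def test_left_right_outlines_mirror(self):
        r = make_insole_surface(side="right")
        l = make_insole_surface(side="left")
        vr = np.asarray(r.outline.exterior.coords)
        vl = np.asarray(l.outline.exterior.coords)
        assert np.allclose(sorted(vr[:, 1]), sorted(-vl[:, 1]))

    def test_outline_foot_shaped(self, flat_surface):
        v = np.asarray(flat_surface.outline.exterior.coords)
        assert flat_surface.outline.is_simple
        L = flat_surface.length_mm
        forefoot = np.ptp(v[v[:, 0] > 0.7 * L, 1])
        heel = np.ptp(v[v[:, 0] < 0.3 * L, 1])
        assert forefoot > heel

    def test_grid_points_inside_outline(self, flat_surface):
        import shapely

        inside = shapely.contains_xy(flat_surface.outline,
                                     flat_surface.grid_points[:, 0],
                                     flat_surface.grid_points[:, 1])
        assert inside.all()

    @pytest.mark.parametrize("kwargs", [
        {"length_mm": -10.0}, {"width_mm": 0.0},
        {"length_mm": 80.0, "width_mm": 95.0},  # width >= length
        {"arch_height_mm": -1.0}, {"thickness_mm": 0.0},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(InvalidGeometry):
            make_insole_surface(**kwargs)


class TestDeformation:
    def test_empty_bump_list_is_zero_field(self, flat_surface):
        d = make_deformation(flat_surface, [])
        assert np.all(d.displacement == 0.0)
        assert np.all(d.strain_truth.S_MAG.values == 0.0)

    def test_indentation_sets_out_of_plane_strain(self, flat_surface):
        # 1 mm indentation on the 5 mm layer: S_Z peaks at 0.20
        d = make_deformation(flat_surface, [Bump("heel", (35.0, 0.0), 12.0,
                                                 0.0, 1.0)])
        assert d.strain_truth.S_Z.max() == pytest.approx(0.20, abs=0.005)

    def test_superposition_of_distant_bumps(self, flat_surface):
        b1 = Bump("heel", (35.0, 0.0), 8.0, 0.04, 0.5)
        b2 = Bump("hallux", (230.0, 20.0), 8.0, 0.02, 0.3)
        both = make_deformation(flat_surface, [b1, b2])
        one = make_deformation(flat_surface, [b1])
        two = make_deformation(flat_surface, [b2])
        np.testing.assert_allclose(both.displacement,
                                   one.displacement + two.displacement,
                                   atol=1e-12)
        np.testing.assert_allclose(
            both.strain_truth.S_MAG.values,
            (one.strain_truth.S_MAG + two.strain_truth.S_MAG).values, atol=1e-4)

    def test_strain_truth_consistent_with_finite_differences(self, flat_surface):
        d = make_deformation(flat_surface, [Bump("heel", (40.0, 0.0), 10.0,
                                                 0.05, 0.8)])
        h = 0.5
        xs = np.arange(20.0, 60.0, h)
        ys = np.arange(-15.0, 15.0, h)
        GX, GY = np.meshgrid(xs, ys, indexing="ij")
        u = d.displacement_at(np.column_stack([GX.ravel(), GY.ravel()]))
        U = u.reshape(*GX.shape, 3)
        dux = np.gradient(U[..., 0], h, axis=0)
        duy = np.gradient(U[..., 0], h, axis=1)
        dvx = np.gradient(U[..., 1], h, axis=0)
        dvy = np.gradient(U[..., 1], h, axis=1)
        F11, F12, F21, F22 = 1 + dux, duy, dvx, 1 + dvy
        E11 = 0.5 * (F11**2 + F21**2 - 1)
        # analytic truth at the same points
        t = syn._strain_truth_table(
            type("S", (), {"grid_points": np.column_stack(
                [GX.ravel(), GY.ravel(), np.zeros(GX.size)]),
                "thickness_mm": flat_surface.thickness_mm})(),
            d.displacement_fn)
        interior = (slice(2, -2), slice(2, -2))
        assert np.max(np.abs(E11[interior]
                             - t.E_ap.values.reshape(GX.shape)[interior])) < 1e-3

    def test_bump_outside_outline_rejected(self, flat_surface):
        with pytest.raises(BumpOutsideInsole):
            make_deformation(flat_surface, [Bump(None, (-50.0, 0.0), 5.0, 0.01, 0.1)])
        with pytest.raises(BumpOutsideInsole):
            make_deformation(flat_surface, [Bump(None, (35.0, 0.0), -1.0, 0.01, 0.1)])


class TestRendering:
    def test_rendering_is_pure(self, flat_surface, rig640, flat_pre_pair):
        again = render_stereo_pair(flat_surface, None, *rig640)
        np.testing.assert_array_equal(flat_pre_pair[0], again[0])
        np.testing.assert_array_equal(flat_pre_pair[1], again[1])

    def test_identical_cameras_identical_images(self, flat_surface, rig640):
        cam1 = rig640[0]
        a, b = render_stereo_pair(flat_surface, None, cam1, cam1)
        np.testing.assert_array_equal(a, b)

    def test_rigid_translation_shifts_image_content(self, flat_surface):
        # fronto-parallel camera: t mm translates content by t * f / z px,
        # recovered by (plain, unwhitened) phase correlation on an
        # interior crop
        f, z = 740.7407, 400.0
        C = np.array([130.0, 0.0, z])
        R = syn._look_at(C, np.array([130.0, 0.0, 0.0]))
        cam = CameraModel(f, (319.5, 199.5), R, -R @ C, (640, 400))
        t_mm = 2.0
        d = rigid_translation_deformation(flat_surface, (t_mm, 0.0, 0.0))
        a, _ = render_stereo_pair(flat_surface, None, cam, cam)
        b, _ = render_stereo_pair(flat_surface, d, cam, cam)
        w = (slice(160, 240), slice(150, 500))
        shift, _, _ = phase_cross_correlation(a[w].astype(float),
                                              b[w].astype(float),
                                              upsample_factor=500,
                                              normalization=None)
        assert abs(-shift[1] - t_mm * f / z) < 0.05
        assert abs(shift[0]) < 0.05


class TestSimulateStudy:
    def test_zero_noise_reproduces_truth_exactly(self):
        profile = default_effect_profile()
        table, _ = simulate_study(StudyDesign(seed=1), profile, noise_cv=0.0)
        for region in ("heel", "hallux", "mth3"):
            for cond in ("flat", "low_stiffness"):
                vals = table[(table.region == region)
                             & (table.condition == cond)].peak_smag_pct
                assert np.allclose(vals, profile.loc[region, cond])

    def test_table_shape_matches_design(self):
        table, _ = simulate_study(StudyDesign(seed=2), default_effect_profile(),
                                  noise_cv=0.1)
        regional = table[table.region != "global"]
        assert len(regional) == 5 * 3 * 3 * 11
        assert len(table[table.region == "global"]) == 5 * 3 * 3
        keys = table.groupby(["participant", "condition", "repeat", "region"]).size()
        assert (keys == 1).all()

    def test_negative_truth_rejected(self):
        profile = default_effect_profile()
        profile.loc["heel", "flat"] = -1.0
        with pytest.raises(InvalidEffectProfile):
            simulate_study(StudyDesign(seed=1), profile, noise_cv=0.1)

    def test_median_of_medians_recovers_truth(self):
        # Monte-Carlo: repeated studies, cohort median-of-medians estimate
        profile = default_effect_profile()
        profile.loc["heel", "flat"] = 12.0
        profile.loc["heel", "low_stiffness"] = 20.0
        ests = []
        for i in range(300):
            table, _ = simulate_study(StudyDesign(seed=40_000 + i), profile,
                                      noise_cv=0.05)
            sub = table[(table.region == "heel") & (table.condition == "flat")]
            per = sub.groupby("participant").peak_smag_pct.median()
            ests.append(per.median())
        assert abs(np.median(ests) - 12.0) < 2.0  # within 2 strain-% of truth
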