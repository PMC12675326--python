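"""Plantar mask template construction, registration and region assignment."""

import numpy as np
import pytest

from stamps3d import (
    MaskTemplateConfig,
    assign_regions,
    build_default_template,
    fit_anatomical_frame,
    make_insole_surface,
    register_mask,
)
from stamps3d.errors import InvalidTemplateConfig, RegistrationFailed
from stamps3d.mask import registered_region_polygons
from stamps3d.regions import REGIONS


@pytest.fixture(scope="module")
def template():
    return build_default_template()


@pytest.fixture(scope="module")
def scene():
    surface = make_insole_surface()
    frame = fit_anatomical_frame(surface.outline, "right")
    return surface, frame


class TestTemplate:
    def test_eleven_regions_partition_unit_domain(self, template):
        assert len(template.regions) == 11
        assert set(template.regions) == set(REGIONS)
        total = sum(p.area for p in template.regions.values())
        assert total == pytest.approx(template.domain.area, rel=1e-9)

    def test_heel_band_membership(self, template):
        from shapely.geometry import Point

        assert template.regions["heel"].covers(Point(0.1, 0.0))
        assert not template.regions["heel"].covers(Point(0.5, 0.0))

    def test_medial_regions_on_medial_side(self, template):
        # medial is +ML: hallux, mth1 and the medial midfoot sit there
        for name in ("hallux", "mth1", "midfoot_medial"):
            assert template.regions[name].centroid.y > 0

    @pytest.mark.parametrize("kwargs", [
        {"heel_band": (0.0, 0.6), "midfoot_band": (0.5, 0.7)},  # overlap
        {"midfoot_medial_width": 1.5},
        {"mth_widths": (0.5, 0.2, 0.2, 0.2, 0.2)},  # sums > 1
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(InvalidTemplateConfig):
            build_default_template(MaskTemplateConfig(**kwargs))


class TestRegistration:
    def test_unit_length_outline_gives_unit_scale(self, template, scene):
        surface, _ = scene
        v = np.asarray(surface.outline.exterior.coords)[:-1] / surface.length_mm
        frame = fit_anatomical_frame(v, "right")
        tr = register_mask(template, v, "right", frame)
        assert tr.scale_ap == pytest.approx(1.0, abs=0.02)
        assert abs(tr.rotation_deg) < 3.0

    def test_known_scale_and_rotation_recovered(self, template, scene):
        surface, frame = scene
        tr0 = register_mask(template, surface.outline, "right", frame)
        v = np.asarray(surface.outline.exterior.coords)[:-1]
        th = np.deg2rad(15.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        v2 = 1.2 * (v @ R.T)
        fr2 = fit_anatomical_frame(v2, "right")
        tr2 = register_mask(template, v2, "right", fr2)
        assert tr2.scale_ap / tr0.scale_ap == pytest.approx(1.2, abs=0.01)
        assert tr2.rotation_deg - tr0.rotation_deg == pytest.approx(15.0, abs=0.5)

    def test_left_foot_mirror_flag_and_mth1_medial(self, template):
        surface = make_insole_surface(side="left")
        frame = fit_anatomical_frame(surface.outline, "left")
        tr = register_mask(template, surface.outline, "left", frame)
        assert tr.mirror
        c = np.asarray(template.regions["mth1"].centroid.coords)[0]
        f = tr.template_to_frame(np.array([c]))[0]
        w = frame.origin[:2] + f[0] * frame.ap_axis[:2] + f[1] * frame.ml_axis[:2]
        assert w[1] < 0  # medial edge of a left foot is at -y world

    def test_degenerate_outline_rejected(self, template):
        line = np.column_stack([np.linspace(0, 100, 50), np.zeros(50)])
        frame = fit_anatomical_frame(line, "right", heel_end_hint=(0.0, 0.0))
        with pytest.raises(RegistrationFailed):
            register_mask(template, line, "right", frame)


class TestAssignment:
    def test_heel_point_labelled_heel(self, template, scene):
        surface, frame = scene
        tr = register_mask(template, surface.outline, "right", frame)
        f = tr.template_to_frame(np.array([[0.1, 0.0]]))[0]
        w = frame.origin[:2] + f[0] * frame.ap_axis[:2] + f[1] * frame.ml_axis[:2]
        asg = assign_regions(np.array([[w[0], w[1], 0.0]]), tr, template,
                             outline=surface.outline)
        assert asg.labels[0] == "heel"

    def test_boundary_points_resolved_deterministically(self, template, scene):
        surface, frame = scene
        tr = register_mask(template, surface.outline, "right", frame)
        # points exactly on the medial/lateral midfoot split line
        split = 0.5 - template.config.midfoot_medial_width
        tpts = np.column_stack([np.linspace(0.3, 0.5, 7),
                                np.full(7, split)])
        f = tr.template_to_frame(tpts)
        w = (frame.origin[:2] + f[:, :1] * frame.ap_axis[:2]
             + f[:, 1:] * frame.ml_axis[:2])
        a1 = assign_regions(w, tr, template)
        a2 = assign_regions(w, tr, template)
        assert list(a1.labels) == list(a2.labels)
        # precedence order: midfoot_medial is declared before midfoot_lateral
        assert set(a1.labels) == {"midfoot_medial"}

    def test_label_counts_proportional_to_areas(self, template, scene):
        surface, frame = scene
        tr = register_mask(template, surface.outline, "right", frame)
        rng = np.random.default_rng(0)
        tpts = rng.uniform([0.0, -0.5], [1.0, 0.5], (10_000, 2))
        f = tr.template_to_frame(tpts)
        w = (frame.origin[:2] + f[:, :1] * frame.ap_axis[:2]
             + f[:, 1:] * frame.ml_axis[:2])
        counts = assign_regions(w, tr, template).counts()
        for name in REGIONS:
            assert counts[name] / 10_000 == pytest.approx(
                template.regions[name].area, abs=0.02)

    def test_partition_closes_outline_area(self, template, scene):
        surface, frame = scene
        tr = register_mask(template, surface.outline, "right", frame)
        polys = registered_region_polygons(template, tr, surface.outline)
        total = sum(p.area for p in polys.values())
        assert total == pytest.approx(surface.outline.area, rel=0.005)

    def test_registration_equivariance_of_labels(self, template, scene):
        surface, frame = scene
        tr = register_mask(template, surface.outline, "right", frame)
        base = assign_regions(surface.grid_points, tr, template,
                              outline=surface.outline)
        v = np.asarray(surface.outline.exterior.coords)[:-1]
        th = np.deg2rad(15.0)
        R3 = np.array([[np.cos(th), -np.sin(th), 0],
                       [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        v2 = 1.2 * (v @ R3[:2, :2].T)
        pts2 = 1.2 * (surface.grid_points @ R3.T)
        fr2 = fit_anatomical_frame(v2, "right")
        tr2 = register_mask(template, v2, "right", fr2)
        moved = assign_regions(pts2, tr2, template)
        changed = np.mean(base.labels != moved.labels)
        assert changed < 0.01

    def test_mirror_consistency_of_labels(self, template, scene):
        surface, frame = scene
        tr = register_mask(template, surface.outline, "right", frame)
        base = assign_regions(surface.grid_points, tr, template,
                              outline=surface.outline)
        M = np.diag([1.0, -1.0, 1.0])
        v = np.asarray(surface.outline.exterior.coords)[:-1] * [1.0, -1.0]
        frl = fit_anatomical_frame(v, "left")
        trl = register_mask(template, v, "left", frl)
        mirrored = assign_regions(surface.grid_points @ M, trl, template)
        assert np.mean(base.labels != mirrored.labels) < 0.005
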