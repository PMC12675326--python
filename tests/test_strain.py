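"""Anatomical frame fitting, Green-Lagrange surface strain, bracket maps."""

from types import SimpleNamespace

import numpy as np
import pytest

from stamps3d import (
    Bump,
    bracket_map,
    compute_surface_strain,
    fit_anatomical_frame,
    make_deformation,
    make_insole_surface,
    uniform_stretch_deformation,
)
from stamps3d.errors import AmbiguousOrientation, EmptyStrainField
from stamps3d.strain import bracket_names
from stamps3d.synthetic import smag_percent


def _field(points, displacements):
    return SimpleNamespace(ref_points_3d=points, displacements_3d=displacements,
                           valid=np.ones(len(points), dtype=bool))


@pytest.fixture(scope="module")
def surface():
    return make_insole_surface(grid_spacing_mm=3.0)


@pytest.fixture(scope="module")
def frame(surface):
    return fit_anatomical_frame(surface.outline, "right")


class TestAnatomicalFrame:
    def test_anterior_points_to_wide_end(self, frame):
        # forefoot (wide end) is at +x in the generator's convention
        assert frame.ap_axis[0] > 0.95

    def test_rotation_equivariance(self, surface, frame):
        v = np.asarray(surface.outline.exterior.coords)[:-1]
        th = np.deg2rad(37.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        fr = fit_anatomical_frame(v @ R.T, "right")
        base = np.degrees(np.arctan2(frame.ap_axis[1], frame.ap_axis[0]))
        rot = np.degrees(np.arctan2(fr.ap_axis[1], fr.ap_axis[0]))
        assert rot - base == pytest.approx(37.0, abs=0.1)

    def test_mirror_outlines_flip_ml_axis(self, surface, frame):
        v = np.asarray(surface.outline.exterior.coords)[:-1]
        mirrored = v * [1.0, -1.0]
        fl = fit_anatomical_frame(mirrored, "left")
        # both axes map through the mirror: medial stays anatomically medial
        M = np.diag([1.0, -1.0, 1.0])
        assert np.allclose(fl.ap_axis, M @ frame.ap_axis, atol=1e-6)
        assert np.allclose(fl.ml_axis, M @ frame.ml_axis, atol=1e-6)

    def test_near_circular_outline_ambiguous(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = np.column_stack([np.cos(t), np.sin(t)])
        with pytest.raises(AmbiguousOrientation):
            fit_anatomical_frame(circle, "right")
        # a heel hint resolves it
        fr = fit_anatomical_frame(circle, "right", heel_end_hint=(-1.0, 0.0))
        assert fr.ap_axis[0] > 0


class TestSurfaceStrain:
    def test_uniform_stretch_closed_form(self, surface, frame):
        lam = 1.05
        d = uniform_stretch_deformation(surface, lam)
        sf = compute_surface_strain(_field(surface.grid_points, d.displacement),
                                    frame)
        v = sf.valid
        assert np.nanmean(sf.E_ap[v]) == pytest.approx((lam**2 - 1) / 2, abs=5e-4)
        assert np.nanmean(sf.S_ANT[v]) == pytest.approx(5.125, abs=0.05)
        assert np.nanmax(sf.S_POST[v]) == 0.0

    def test_rigid_rotation_strain_free(self, surface, frame):
        th = np.deg2rad(10.0)
        c = surface.grid_points.mean(axis=0)
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        disp = (surface.grid_points - c) @ R.T + c - surface.grid_points
        sf = compute_surface_strain(_field(surface.grid_points, disp), frame)
        assert np.nanmax(sf.S_MAG[sf.valid]) < 0.2

    def test_zero_displacement_zero_strain(self, surface, frame):
        sf = compute_surface_strain(
            _field(surface.grid_points, np.zeros_like(surface.grid_points)), frame)
        v = sf.valid
        for comp in (sf.S_MAG, sf.S_ANT, sf.S_POST, sf.S_MED, sf.S_LAT, sf.S_Z):
            assert np.nanmax(np.abs(comp[v])) < 1e-10

    def test_magnitude_combines_components(self):
        # 3-4-5 triangle: E_ap 0.03, E_ml 0.04 -> S_MAG 5.0%
        assert smag_percent(0.03, 0.04, 0.0, 0.0) == pytest.approx(5.0)
        assert smag_percent(0.0, 0.0, 0.0, 0.2) == pytest.approx(20.0)

    def test_magnitude_unbounded_above(self):
        # large deformation: no clipping at 100%
        assert smag_percent(0.9, 0.6, 0.0, 0.5) > 100.0

    def test_bump_field_recovery(self, surface, frame):
        d = make_deformation(surface, [Bump("heel", (40.0, 0.0), 14.0, 0.05, 0.8)])
        sf = compute_surface_strain(_field(surface.grid_points, d.displacement),
                                    frame)
        v = sf.valid
        truth = d.strain_truth.S_MAG.values
        r = np.corrcoef(sf.S_MAG[v], truth[v])[0, 1]
        assert r > 0.95
        peak_est = surface.grid_points[np.nanargmax(np.where(v, sf.S_MAG, -np.inf)), :2]
        peak_truth = surface.grid_points[np.argmax(truth), :2]
        assert np.linalg.norm(peak_est - peak_truth) < 3.5  # one grid step

    def test_directional_parts_mutually_exclusive(self, surface, frame):
        d = make_deformation(surface, [Bump("heel", (40.0, 0.0), 14.0, 0.05, 0.8)])
        sf = compute_surface_strain(_field(surface.grid_points, d.displacement),
                                    frame)
        v = sf.valid
        assert np.all(sf.S_ANT[v] >= 0) and np.all(sf.S_POST[v] >= 0)
        assert np.all((sf.S_ANT[v] == 0) | (sf.S_POST[v] == 0))
        assert np.all((sf.S_MED[v] == 0) | (sf.S_LAT[v] == 0))

    def test_all_invalid_raises(self, surface, frame):
        fld = SimpleNamespace(ref_points_3d=surface.grid_points,
                              displacements_3d=np.zeros_like(surface.grid_points),
                              valid=np.zeros(len(surface.grid_points), dtype=bool))
        with pytest.raises(EmptyStrainField):
            compute_surface_strain(fld, frame)


class TestBrackets:
    def test_one_node_per_default_bracket(self):
        labels, fracs = bracket_map(np.array([1.0, 3.0, 6.0, 8.0, 11.0]))
        assert list(labels) == [0, 1, 2, 3, 4]
        assert np.allclose(fracs, 0.2)

    def test_boundary_value_goes_to_upper_bracket(self):
        labels, _ = bracket_map(np.array([2.5]))
        assert labels[0] == 1  # half-open [lo, hi) convention

    def test_degenerate_all_zero_field(self):
        _, fracs = bracket_map(np.zeros(10))
        assert fracs[0] == 1.0 and fracs[1:].sum() == 0.0

    def test_fractions_partition_unity(self):
        rng = np.random.default_rng(0)
        _, fracs = bracket_map(rng.uniform(0, 30, 500))
        assert fracs.sum() == pytest.approx(1.0)

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            bracket_map(np.array([1.0]), edges=(0.0, 5.0, 2.5))

    def test_bracket_names(self):
        names = bracket_names()
        assert names[0] == "0-2.5%" and names[-1] == ">10%"
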