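"""Projection model and triangulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrlqc.geometry import (
    BeamGeometry,
    FiducialPolar,
    GantryProjectionSet,
    PanelPoint,
    iec_to_polar,
    pixels_to_isocenter_mm,
    polar_to_iec,
    project_fiducial,
    triangulate_fiducial,
)

ANGLES4 = (0.0, 90.0, 180.0, 270.0)


def _project_set(f, geom, angles=ANGLES4, noise=None, rng=None):
    pts = []
    for a in angles:
        p = project_fiducial(f, a, geom)
        if noise:
            pts.append(
                PanelPoint(
                    p.u_iso + rng.normal(0, noise),
                    p.v_iso + rng.normal(0, noise),
                    a,
                )
            )
        else:
            pts.append(p)
    return GantryProjectionSet(tuple(pts))


class TestProjection:
    def test_on_axis_fiducial_projects_to_isocenter(self, geom):
        for phi in (0.0, 37.0, 180.0):
            p = project_fiducial(FiducialPolar(123.0, 0.0, 0.0), phi, geom)
            assert p.u_iso == pytest.approx(0.0, abs=1e-12)
            assert p.v_iso == pytest.approx(0.0, abs=1e-12)

    def test_on_axis_longitudinal_offset_has_unit_magnification(self, geom):
        p = project_fiducial(FiducialPolar(10.0, 0.0, 5.0), 120.0, geom)
        assert p.u_iso == pytest.approx(0.0, abs=1e-12)
        assert p.v_iso == pytest.approx(5.0, abs=1e-12)

    def test_quadrature_geometry_cancels_denominator(self, geom):
        # theta - phi = 90 deg: the cosine term vanishes
        p = project_fiducial(FiducialPolar(90.0, 100.0, 10.0), 0.0, geom)
        assert p.u_iso == pytest.approx(100.0, abs=1e-9)
        assert p.v_iso == pytest.approx(10.0, abs=1e-9)

    def test_fiducial_toward_source_magnified(self, geom):
        # direct evaluation of the closed form at theta - phi = 0
        sad, r, y = geom.sad, 100.0, 10.0
        p = project_fiducial(FiducialPolar(40.0, r, y), 40.0, geom)
        assert p.u_iso == pytest.approx(0.0, abs=1e-9)
        assert p.v_iso == pytest.approx(sad * y / (sad - r), rel=1e-12)
        assert abs(p.v_iso) >= abs(y)  # magnification toward the source
        p2 = project_fiducial(FiducialPolar(40.0, r, y), 220.0, geom)
        assert abs(p2.v_iso) <= abs(y)  # de-magnification away from it

    def test_r_at_least_sad_rejected(self, geom):
        with pytest.raises(ValueError, match="degenerate"):
            project_fiducial(FiducialPolar(0.0, geom.sad, 0.0), 0.0, geom)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0, 360, exclude_max=True),
        r=st.floats(0, 120),
        y=st.floats(-40, 40),
        phi=st.floats(0, 360),
        delta=st.floats(-360, 360),
    )
    def test_gantry_shift_equivariance(self, geom, theta, r, y, phi, delta):
        f1 = project_fiducial(FiducialPolar(theta, r, y), phi, geom)
        f2 = project_fiducial(
            FiducialPolar((theta + delta) % 360.0, r, y), phi + delta, geom
        )
        assert f1.u_iso == pytest.approx(f2.u_iso, abs=1e-8)
        assert f1.v_iso == pytest.approx(f2.v_iso, abs=1e-8)

    def test_small_r_limit_v_tends_to_y(self, geom):
        for phi in (0.0, 45.0, 200.0):
            p = project_fiducial(FiducialPolar(77.0, 1e-9, 12.0), phi, geom)
            assert p.v_iso == pytest.approx(12.0, abs=1e-9)


class TestPixelConversion:
    @pytest.mark.parametrize(
        "px,mm", [(0.0, 0.0), (1.0, 0.2163), (11.0, 2.3793), (-3.5, -0.75705)]
    )
    def test_pixel_to_mm(self, geom, px, mm):
        assert pixels_to_isocenter_mm(px, geom) == pytest.approx(mm, abs=1e-12)


class TestPolarCartesian:
    def test_degenerate_radius_maps_to_axis(self):
        v = polar_to_iec(FiducialPolar(211.0, 0.0, 4.0))
        assert (v.x, v.y, v.z) == (0.0, 4.0, 0.0)

    def test_zero_azimuth_is_anterior_axis(self):
        v = polar_to_iec(FiducialPolar(0.0, 10.0, 0.0))
        assert v.x == pytest.approx(0.0, abs=1e-12)
        assert v.z == pytest.approx(10.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        theta=st.floats(0, 360, exclude_max=True),
        r=st.floats(0.01, 120),
        y=st.floats(-40, 40),
    )
    def test_polar_iec_bijection(self, theta, r, y):
        f = FiducialPolar(theta, r, y)
        back = iec_to_polar(polar_to_iec(f))
        assert back.r == pytest.approx(r, abs=1e-9)
        assert back.y == pytest.approx(y, abs=1e-12)
        assert abs((back.theta - theta + 180) % 360 - 180) < 1e-6 * max(1, 1 / r)


class TestTriangulation:
    def test_noiseless_round_trip(self, geom):
        f = FiducialPolar(30.0, 50.0, 12.0)
        polar, iec, rms = triangulate_fiducial(_project_set(f, geom), geom)
        assert polar.theta == pytest.approx(30.0, abs=1e-6)
        assert polar.r == pytest.approx(50.0, abs=1e-6)
        assert polar.y == pytest.approx(12.0, abs=1e-6)
        assert rms < 1e-6
        truth = polar_to_iec(f)
        assert np.allclose(iec.as_array(), truth.as_array(), atol=1e-6)

    def test_on_axis_observations_give_degenerate_azimuth(self, geom):
        pts = tuple(PanelPoint(0.0, 3.0, a) for a in ANGLES4)
        polar, iec, rms = triangulate_fiducial(GantryProjectionSet(pts), geom)
        assert polar.r == pytest.approx(0.0, abs=1e-9)
        assert polar.y == pytest.approx(3.0, abs=1e-9)
        assert not polar.theta_defined

    def test_two_angles_suffice(self, geom):
        f = FiducialPolar(290.0, 20.0, -8.0)
        polar, _, _ = triangulate_fiducial(_project_set(f, geom, (0.0, 90.0)), geom)
        assert polar.r == pytest.approx(20.0, abs=1e-6)
        assert abs((polar.theta - 290.0 + 180) % 360 - 180) < 1e-6

    def test_single_angle_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            GantryProjectionSet((PanelPoint(0, 0, 10.0), PanelPoint(1, 1, 370.0)))

    def test_noisy_recovery_monte_carlo(self, geom):
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            f = FiducialPolar(
                rng.uniform(0, 360), rng.uniform(1, 50), rng.uniform(-25, 25)
            )
            pset = _project_set(f, geom, noise=0.05, rng=rng)
            _, iec, _ = triangulate_fiducial(pset, geom)
            errs.append(np.linalg.norm(iec.as_array() - polar_to_iec(f).as_array()))
        assert np.mean(errs) < 0.1
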