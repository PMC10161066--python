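"""MV portal image analysis: field isolation, fiducial localization,
edge detection, couch marker."""

import numpy as np
import pytest

from mrlqc.geometry import Vec3IEC
from mrlqc.mv_analysis import (
    AmbiguousDetectionError,
    CouchMarkerError,
    FiducialNotFoundError,
    MVImage,
    N_EDGE_PROFILES,
    NoBeamError,
    detect_couch_fiducial,
    detect_field_edges,
    isolate_field_region,
    localize_mv_fiducials,
    profile_strip_width_mm,
)
from mrlqc.plan_io import planned_field_to_panel
from mrlqc.synthetic import (
    COUCH_MARKER_BASELINE_MM,
    ApertureError,
    ScenarioSpec,
    _apply_aperture_error,
    default_reference_plan,
    render_mv_image,
)

ISOLATED_FID = 6  # >=20 mm from any neighbour at gantry 0


def render(spec, geom, scenario=None, beam_index=0, field=None, truth=None):
    scenario = scenario or ScenarioSpec(mv_noise_sigma=0.0, seed=1)
    plan = default_reference_plan()
    field = field or plan.beams[beam_index]
    return render_mv_image(spec, field, scenario, geom, truth=truth)


@pytest.fixture(scope="module")
def noiseless(spec, geom):
    truth = {}
    img = render(spec, geom, truth=truth)
    return img, truth["mv_images"][0]


class TestFieldIsolation:
    def test_uniform_rectangle_bbox_exact(self, geom):
        px = np.zeros((geom.panel_size_px[1], geom.panel_size_px[0]))
        px[100:140, 200:250] = 1.0
        img = MVImage(px, 0.0, geom)
        _, bbox = isolate_field_region(img, 0.5, min_area_px=100)
        assert bbox == (100, 139, 200, 249)

    def test_all_zero_image_is_no_beam(self, geom):
        img = MVImage(np.zeros((geom.panel_size_px[1], geom.panel_size_px[0])), 0.0, geom)
        with pytest.raises(NoBeamError):
            isolate_field_region(img)

    def test_penumbra_bbox_near_50pct_edge(self, spec, geom, noiseless):
        img, truth = noiseless
        _, bbox = isolate_field_region(img)
        iso_u, iso_v = geom.iso_pixel(0.0)
        pr = geom.pixel_resolution
        jaw = truth["delivered_jaw_edges_mm"]
        assert abs((bbox[2] - iso_u) * pr - jaw[0]) < 2 * pr
        assert abs((bbox[3] - iso_u) * pr - jaw[1]) < 2 * pr


class TestFiducialLocalization:
    def test_isolated_fiducial_subpixel_accuracy(self, spec, geom, mv_cfg, templates):
        for dx in (0.0, 0.07, 0.33, 0.49):
            from mrlqc.synthetic import adapt_plan

            sc = ScenarioSpec(mv_noise_sigma=0.0, seed=1, phantom_shift=Vec3IEC(dx, 0.17, 0))
            plan = adapt_plan(default_reference_plan(), sc.phantom_shift)
            truth = {}
            img = render_mv_image(spec, plan.beams[0], sc, geom, truth=truth)
            f = truth["mv_images"][0]["fiducials"][ISOLATED_FID]
            det = localize_mv_fiducials(img, [(f["u_px"], f["v_px"])], mv_cfg, templates)[0]
            assert abs(det.u - f["u_px"]) <= 0.05
            assert abs(det.v - f["v_px"]) <= 0.05

    def test_realistic_noise_mean_error_under_tenth_pixel(self, spec, geom, mv_cfg, templates):
        errs = []
        for seed in range(12):
            truth = {}
            img = render(spec, geom, ScenarioSpec(mv_noise_sigma=0.01, seed=seed), truth=truth)
            for i in (3, 5, 6):
                f = truth["mv_images"][0]["fiducials"][i]
                det = localize_mv_fiducials(img, [(f["u_px"], f["v_px"])], mv_cfg, templates)[0]
                errs.append((abs(det.u - f["u_px"]), abs(det.v - f["v_px"])))
        mean = np.mean(errs, axis=0)
        assert mean[0] <= 0.1 and mean[1] <= 0.1

    def test_missing_fiducial_raises(self, spec, geom, mv_cfg, templates, noiseless):
        img, _ = noiseless
        iso_u, iso_v = geom.iso_pixel(0.0)
        # in-field position with no fiducial anywhere near
        eu = iso_u - 25.0 / geom.pixel_resolution
        ev = iso_v - 10.0 / geom.pixel_resolution
        with pytest.raises((FiducialNotFoundError, AmbiguousDetectionError)):
            localize_mv_fiducials(img, [(eu, ev)], mv_cfg, templates)

    def test_intensity_scale_invariance(self, spec, geom, mv_cfg, templates, noiseless):
        img, truth = noiseless
        f = truth["fiducials"][ISOLATED_FID]
        d1 = localize_mv_fiducials(img, [(f["u_px"], f["v_px"])], mv_cfg, templates)[0]
        scaled = MVImage(img.pixels * 7.3, img.gantry_angle, geom)
        d2 = localize_mv_fiducials(scaled, [(f["u_px"], f["v_px"])], mv_cfg, templates)[0]
        assert d1.u == pytest.approx(d2.u, abs=1e-9)
        assert d1.v == pytest.approx(d2.v, abs=1e-9)

    def test_integer_shift_equivariance(self, spec, geom, mv_cfg, templates, noiseless):
        img, truth = noiseless
        f = truth["fiducials"][ISOLATED_FID]
        d1 = localize_mv_fiducials(img, [(f["u_px"], f["v_px"])], mv_cfg, templates)[0]
        shifted = MVImage(np.roll(img.pixels, (3, -5), axis=(0, 1)), 0.0, geom)
        d2 = localize_mv_fiducials(
            shifted, [(f["u_px"] - 5, f["v_px"] + 3)], mv_cfg, templates
        )[0]
        assert d2.u - d1.u == pytest.approx(-5.0, abs=0.02)
        assert d2.v - d1.v == pytest.approx(3.0, abs=0.02)


class TestFieldEdges:
    def test_profile_strip_width_matches_panel_pitch(self, geom):
        assert N_EDGE_PROFILES == 11
        assert profile_strip_width_mm(geom) == pytest.approx(2.3793, abs=1e-12)

    def test_noiseless_edges_within_tenth_mm(self, spec, geom, mv_cfg, noiseless):
        img, truth = noiseless
        planned = planned_field_to_panel(default_reference_plan().beams[0], geom)
        m = detect_field_edges(img, planned, geom, mv_cfg)
        jaw = truth["delivered_jaw_edges_mm"]
        assert abs(m.jaw_edges[0] - jaw[0]) < 0.1
        assert abs(m.jaw_edges[1] - jaw[1]) < 0.1
        for k, (a, b) in m.mlc_edges.items():
            ta, tb = truth["delivered_mlc_edges_mm"][str(k)]
            assert abs(a - ta) < 0.1 and abs(b - tb) < 0.1

    def test_symmetric_aperture_center_recovered(self, spec, geom, mv_cfg, noiseless):
        img, _ = noiseless
        planned = planned_field_to_panel(default_reference_plan().beams[0], geom)
        m = detect_field_edges(img, planned, geom, mv_cfg)
        assert abs(m.field_center[0] - planned.field_center[0]) < 0.05
        assert abs(m.field_center[1] - planned.field_center[1]) < 0.05

    def test_phantom_presence_moves_edges_under_two_tenths(self, spec, geom, mv_cfg):
        """Mirrors the with/without-phantom comparison: the attenuation
        pattern of the phantom must not displace detected MLC edges."""
        plan = default_reference_plan()
        planned = planned_field_to_panel(plan.beams[0], geom)
        sc = ScenarioSpec(mv_noise_sigma=0.0, seed=1)
        with_ph = render_mv_image(spec, plan.beams[0], sc, geom)
        import dataclasses

        empty = dataclasses.replace(spec, body_attenuation=0.0, fiducial_attenuation=0.0)
        without = render_mv_image(empty, plan.beams[0], sc, geom)
        m1 = detect_field_edges(with_ph, planned, geom, mv_cfg)
        m2 = detect_field_edges(without, planned, geom, mv_cfg)
        for k in m1.mlc_edges:
            d = np.subtract(m1.mlc_edges[k], m2.mlc_edges[k])
            assert np.abs(d).max() <= 0.2

    def test_absent_field_propagates_no_beam(self, spec, geom, mv_cfg):
        img = MVImage(
            np.zeros((geom.panel_size_px[1], geom.panel_size_px[0])), 0.0, geom
        )
        planned = planned_field_to_panel(default_reference_plan().beams[0], geom)
        with pytest.raises(NoBeamError):
            detect_field_edges(img, planned, geom, mv_cfg)

    def test_introduced_leaf_offset_detected(self, spec, geom, mv_cfg):
        plan = default_reference_plan()
        planned = planned_field_to_panel(plan.beams[0], geom)
        err = ApertureError(leaf_offsets={0: (0.0, 4.0), 2: (-3.0, 0.0)})
        delivered = _apply_aperture_error(plan.beams[0], err)
        img = render_mv_image(spec, delivered, ScenarioSpec(mv_noise_sigma=0.01, seed=4), geom)
        m = detect_field_edges(img, planned, geom, mv_cfg)
        assert m.mlc_edges[0][1] - planned.mlc_edges[0][1] == pytest.approx(4.0, abs=0.3)
        assert m.mlc_edges[2][0] - planned.mlc_edges[2][0] == pytest.approx(-3.0, abs=0.3)


class TestCouchMarker:
    def _roi(self, geom, tolerances):
        bu, bv = geom.iso_mm_to_pixel(*tolerances.couch_baseline_mm, 0.0)
        half = int(round(tolerances.couch_roi_half_mm / geom.pixel_resolution))
        return (
            int(round(bv)) - half, int(round(bv)) + half + 1,
            int(round(bu)) - half, int(round(bu)) + half + 1,
        )

    def test_marker_at_baseline_gives_zero_delta(self, spec, geom, mv_cfg, tolerances, noiseless):
        img, _ = noiseless
        det = detect_couch_fiducial(img, self._roi(geom, tolerances), COUCH_MARKER_BASELINE_MM, mv_cfg)
        assert abs(det.delta_from_baseline[0]) < 0.05
        assert abs(det.delta_from_baseline[1]) < 0.05

    @pytest.mark.parametrize("shift", [(0.5, 0.0), (-0.31, 0.42)])
    def test_marker_shift_recovered(self, spec, geom, mv_cfg, tolerances, shift):
        sc = ScenarioSpec(mv_noise_sigma=0.01, couch_shift=shift, seed=9)
        img = render(spec, geom, sc)
        det = detect_couch_fiducial(img, self._roi(geom, tolerances), COUCH_MARKER_BASELINE_MM, mv_cfg)
        assert det.delta_from_baseline[0] == pytest.approx(shift[0], abs=0.05)
        assert det.delta_from_baseline[1] == pytest.approx(shift[1], abs=0.05)

    def test_marker_outside_roi_rejected(self, spec, geom, mv_cfg, tolerances, noiseless):
        img, _ = noiseless
        v0, v1, u0, u1 = self._roi(geom, tolerances)
        with pytest.raises(CouchMarkerError):
            # ROI displaced so the marker sits on its border
            detect_couch_fiducial(
                img, (v0 + 20, v1 + 20, u0 + 20, u1 + 20), COUCH_MARKER_BASELINE_MM, mv_cfg
            )
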