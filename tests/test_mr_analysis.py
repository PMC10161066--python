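"""MR volume analysis: phantom corner search and sub-voxel void
localization."""

import dataclasses

import numpy as np
import pytest

from mrlqc.geometry import Vec3IEC
from mrlqc.mr_analysis import (
    MRFiducialNotFoundError,
    MRVolume,
    PhantomNotFoundError,
    find_phantom_corner,
    localize_all_mr_fiducials,
    localize_mr_fiducial,
)
from mrlqc.synthetic import ScenarioSpec, render_mr_volume


def render(spec, shift=Vec3IEC(0, 0, 0), noise=0.0, seed=2):
    truth = {}
    sc = ScenarioSpec(mr_noise_sigma=noise, phantom_shift=shift, seed=seed)
    vol = render_mr_volume(spec, sc, truth=truth)
    return vol, truth["mr"]


@pytest.fixture(scope="module")
def noiseless(spec):
    return render(spec)


class TestCorner:
    def test_known_corner_recovered_within_one_voxel(self, spec, noiseless):
        vol, truth = noiseless
        corner = find_phantom_corner(vol)
        assert np.all(
            np.abs(corner.as_array() - truth["phantom_corner_mr_mm"])
            <= np.asarray(vol.spacing)
        )

    def test_empty_volume_rejected(self):
        vol = MRVolume(np.zeros((20, 20, 20)), (1, 1, 1), Vec3IEC(0, 0, 0))
        with pytest.raises(PhantomNotFoundError):
            find_phantom_corner(vol)

    def test_translation_equivariance(self, spec, noiseless):
        vol, _ = noiseless
        c0 = find_phantom_corner(vol)
        vol_shift, _ = render(spec, shift=Vec3IEC(0, 10, 0))
        c1 = find_phantom_corner(vol_shift)
        assert c1.y - c0.y == pytest.approx(10.0, abs=vol.spacing[1])


class TestLocalizeOne:
    def test_noiseless_sub_voxel_accuracy(self, spec, noiseless):
        vol, truth = noiseless
        for i, tp in enumerate(truth["fiducial_positions_mr_mm"]):
            f = localize_mr_fiducial(vol, Vec3IEC.from_array(np.round(tp)))
            assert np.abs(f.position.as_array() - tp).max() <= 0.1

    def test_sub_voxel_translation_equivariance(self, spec):
        vol0, t0 = render(spec)
        vol1, t1 = render(spec, shift=Vec3IEC(0.3, 0.3, 0.3))
        for i in range(7):
            p0 = localize_mr_fiducial(vol0, Vec3IEC.from_array(t0["fiducial_positions_mr_mm"][i]))
            p1 = localize_mr_fiducial(vol1, Vec3IEC.from_array(t0["fiducial_positions_mr_mm"][i]))
            d = p1.position.as_array() - p0.position.as_array()
            assert np.abs(d - 0.3).max() <= 0.05

    def test_uniform_background_not_found(self, spec, noiseless):
        vol, _ = noiseless
        # center of the bright body, far from any void
        with pytest.raises(MRFiducialNotFoundError):
            localize_mr_fiducial(vol, Vec3IEC(-30, -18, -30))

    def test_noisy_population_mean_error(self, spec):
        """70 void instances with Rician noise: per-axis mean absolute
        error stays within the manual-comparison scale (0.2 mm)."""
        errs = []
        for seed in range(10):
            vol, truth = render(spec, noise=0.03, seed=100 + seed)
            for tp in truth["fiducial_positions_mr_mm"]:
                f = localize_mr_fiducial(vol, Vec3IEC.from_array(np.round(tp)))
                errs.append(np.abs(f.position.as_array() - tp))
        assert len(errs) == 70
        assert np.mean(errs, axis=0).max() <= 0.2

    def test_isotropy_under_half_turn(self, spec, noiseless):
        """Rotating the volume 180 deg about y maps detections to the
        mirrored positions."""
        vol, truth = noiseless
        flipped = MRVolume(
            vol.voxels[::-1, :, ::-1].copy(),
            vol.spacing,
            Vec3IEC(
                -(vol.origin.x + (vol.voxels.shape[0] - 1) * vol.spacing[0]),
                vol.origin.y,
                -(vol.origin.z + (vol.voxels.shape[2] - 1) * vol.spacing[2]),
            ),
        )
        tp = np.array(truth["fiducial_positions_mr_mm"][3])
        mirrored = tp * np.array([-1, 1, -1])
        f = localize_mr_fiducial(flipped, Vec3IEC.from_array(np.round(mirrored)))
        assert np.abs(f.position.as_array() - mirrored).max() <= 0.1


class TestLocalizeAll:
    def test_all_seven_recovered(self, spec, reference_data, noiseless):
        vol, truth = noiseless
        res = localize_all_mr_fiducials(
            vol, reference_data.phantom_model.corner_offsets
        )
        assert not res.errors
        pos = np.array([res.fiducials[i].position.as_array() for i in range(7)])
        rms = np.sqrt(
            np.mean(np.sum((pos - truth["fiducial_positions_mr_mm"]) ** 2, axis=1))
        )
        assert rms <= 0.2

    def test_volume_shift_recovered(self, spec, reference_data):
        vol0, t0 = render(spec)
        vol1, _ = render(spec, shift=Vec3IEC(1, 3, 5))
        offs = reference_data.phantom_model.corner_offsets
        r0 = localize_all_mr_fiducials(vol0, offs)
        r1 = localize_all_mr_fiducials(vol1, offs)
        for i in range(7):
            d = r1.fiducials[i].position.as_array() - r0.fiducials[i].position.as_array()
            assert np.abs(d - (1, 3, 5)).max() <= 0.2

    def test_bad_offset_fails_only_that_fiducial(self, spec, reference_data, noiseless):
        vol, _ = noiseless
        offs = list(reference_data.phantom_model.corner_offsets)
        offs[2] = offs[2] + Vec3IEC(0, 25, 0)  # seed far from any void
        res = localize_all_mr_fiducials(vol, offs)
        assert 2 in res.errors
        assert set(res.fiducials) == {0, 1, 3, 4, 5, 6}


class TestOrientation:
    def test_canonicalization_round_trip(self, spec, noiseless):
        vol, truth = noiseless
        permuted = MRVolume(
            np.transpose(vol.voxels, (1, 2, 0))[:, ::-1, :].copy(),
            (vol.spacing[1], vol.spacing[2], vol.spacing[0]),
            vol.origin,
            orientation=("y", "-z", "x"),
        )
        # the permuted volume's origin must describe voxel (0,0,0): recompute
        nz = vol.voxels.shape[2]
        origin = Vec3IEC(
            vol.origin.x,
            vol.origin.y,
            vol.origin.z + (nz - 1) * vol.spacing[2],
        )
        permuted = MRVolume(permuted.voxels, permuted.spacing, origin, ("y", "-z", "x"))
        canon = permuted.canonical()
        assert canon.voxels.shape == vol.voxels.shape
        assert np.allclose(canon.voxels, vol.voxels)
        assert np.allclose(canon.origin.as_array(), vol.origin.as_array())
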