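"""Phantom characterization, rigid alignment, and shift computation."""

import numpy as np
import pytest

from mrlqc.geometry import Vec3IEC
from mrlqc.registration import (
    CharacterizationError,
    PhantomModel,
    characterize_phantom,
    compute_detected_phantom_shift,
    compute_mr_to_mv_alignment,
)
from mrlqc.synthetic import (
    DEFAULT_ARC_ANGLES,
    _targeted_indices,
    render_characterization_arc,
)


@pytest.fixture(scope="module")
def short_arc(spec):
    """Noiseless reduced arc (every third angle) for round-trip checks."""
    angles = DEFAULT_ARC_ANGLES[::3]
    return render_characterization_arc(spec, angles, noise_sigma=0.0, seed=0)


class TestCharacterization:
    def test_noiseless_round_trip(self, spec, short_arc):
        arc, geom, _ = short_arc
        model = characterize_phantom(arc, spec.fiducial_positions, spec.corner_to_mean)
        mean = np.mean([p.as_array() for p in spec.fiducial_positions], axis=0)
        for i, off in enumerate(model.fiducial_offsets):
            truth = spec.fiducial_positions[i].as_array() - mean
            assert np.abs(off.as_array() - truth).max() <= 0.05

    def test_offsets_sum_to_zero(self, reference_data):
        s = np.sum(
            [o.as_array() for o in reference_data.phantom_model.fiducial_offsets],
            axis=0,
        )
        assert np.abs(s).max() < 1e-9

    def test_plane_partition_and_targets(self, spec, reference_data):
        model = reference_data.phantom_model
        assert sorted(model.plane_assignment) == ["inferior"] * 3 + ["superior"] * 4
        assert model.targeted_indices == _targeted_indices(spec)

    def test_noisy_offsets_within_two_tenths(self, spec, reference_data):
        """The session reference model was characterized from a noisy arc;
        its offsets must still match the design within 0.2 mm."""
        mean = np.mean([p.as_array() for p in spec.fiducial_positions], axis=0)
        for i, off in enumerate(reference_data.phantom_model.fiducial_offsets):
            truth = spec.fiducial_positions[i].as_array() - mean
            assert np.abs(off.as_array() - truth).max() <= 0.2

    def test_characterization_translation_invariance(self, spec, short_arc):
        arc, geom, _ = short_arc
        m1 = characterize_phantom(arc, spec.fiducial_positions, spec.corner_to_mean)
        # feeding translated nominals must not change mean-relative offsets
        shifted = [p + Vec3IEC(0.4, -0.3, 0.2) for p in spec.fiducial_positions]
        m2 = characterize_phantom(arc, shifted, spec.corner_to_mean)
        for a, b in zip(m1.fiducial_offsets, m2.fiducial_offsets):
            assert np.abs(a.as_array() - b.as_array()).max() <= 0.02

    def test_lost_fiducial_aborts_with_index(self, spec, short_arc):
        arc, geom, _ = short_arc
        bad = list(spec.fiducial_positions)
        bad[4] = bad[4] + Vec3IEC(0, 15, 0)  # prediction in empty space
        with pytest.raises(CharacterizationError, match="fiducial 4"):
            characterize_phantom(arc, bad, spec.corner_to_mean)


class TestModelValidation:
    def test_offsets_must_sum_to_zero(self):
        v = Vec3IEC(1.0, 0, 0)
        with pytest.raises(ValueError, match="sum to zero"):
            PhantomModel(
                (v,) * 7, (v,) * 7, ("inferior",) * 3 + ("superior",) * 4, (3, 4)
            )

    def test_model_json_round_trip(self, reference_data):
        model = reference_data.phantom_model
        back = PhantomModel.from_json(model.to_json())
        for a, b in zip(model.fiducial_offsets, back.fiducial_offsets):
            assert np.allclose(a.as_array(), b.as_array())
        assert back.targeted_indices == model.targeted_indices


class TestAlignment:
    def test_exact_translation_recovered_with_zero_residual(self):
        rng = np.random.default_rng(1)
        mv = [Vec3IEC.from_array(rng.uniform(-30, 30, 3)) for _ in range(2)]
        shift = Vec3IEC(0.5, -0.2, 0.3)
        mr = [p + shift for p in mv]
        res = compute_mr_to_mv_alignment(mv, mr)
        assert np.allclose(res.shift.as_array(), shift.as_array(), atol=1e-12)
        assert res.rms_residual == pytest.approx(0.0, abs=1e-12)

    def test_mean_of_differences(self):
        mv = [Vec3IEC(0, 0, 0), Vec3IEC(10, 0, 0)]
        mr = [Vec3IEC(1, 0, 0), Vec3IEC(10, 0, 0)]
        res = compute_mr_to_mv_alignment(mv, mr)
        assert res.shift.x == pytest.approx(0.5)
        assert res.rms_residual > 0

    def test_mismatched_lists_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compute_mr_to_mv_alignment([Vec3IEC(0, 0, 0)] * 3, [Vec3IEC(0, 0, 0)] * 2)

    def test_noisy_recovery_monte_carlo(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(100):
            mv = [Vec3IEC.from_array(rng.uniform(-30, 30, 3)) for _ in range(7)]
            shift = rng.uniform(-2, 2, 3)
            mr = [
                Vec3IEC.from_array(p.as_array() + shift + rng.normal(0, 0.1, 3))
                for p in mv
            ]
            res = compute_mr_to_mv_alignment(mv, mr)
            worst = max(worst, np.abs(res.shift.as_array() - shift).max())
        assert worst <= 0.15

    def test_translation_optimum_matches_grid_search(self):
        """The closed-form RMS optimum equals a brute-force grid search."""
        rng = np.random.default_rng(3)
        mv = [Vec3IEC.from_array(rng.uniform(-10, 10, 3)) for _ in range(4)]
        mr = [Vec3IEC.from_array(p.as_array() + rng.normal(0, 0.5, 3)) for p in mv]
        res = compute_mr_to_mv_alignment(mv, mr)
        a = np.array([p.as_array() for p in mv])
        b = np.array([p.as_array() for p in mr])
        grid = np.arange(-1.5, 1.5, 0.01)
        best = None
        for ax in range(3):
            costs = [
                np.sum((a[:, ax] + g - b[:, ax]) ** 2) for g in grid
            ]  # separable in axes
            g = grid[int(np.argmin(costs))]
            assert abs(g - res.shift.as_array()[ax]) <= 0.01


class TestDetectedShift:
    def test_identity_gives_zero(self):
        pos = [Vec3IEC(1, 2, 3), Vec3IEC(-1, 0, 5)]
        shift, flags = compute_detected_phantom_shift(pos, pos)
        assert np.allclose(shift.as_array(), 0)
        assert not flags

    def test_inconsistent_displacements_flagged(self):
        ref = [Vec3IEC(0, 0, 0), Vec3IEC(10, 0, 0)]
        daily = [Vec3IEC(1.0, 0, 0), Vec3IEC(10.0, 0, 0)]
        shift, flags = compute_detected_phantom_shift(daily, ref)
        assert shift.x == pytest.approx(0.5)
        assert flags and "non-rigid" in flags[0]
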