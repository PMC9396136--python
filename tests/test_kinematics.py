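"""Scaling, inverse kinematics, cycle segmentation and time normalization."""

import numpy as np
import pytest

from squatmech import kinematics as kin
from squatmech.model import DOFS, chain_state, marker_positions, neutral_q, rescale
from squatmech.synthetic import generate_static_trial


class TestClassifyFootPosture:
    @pytest.mark.parametrize("angle,label", [
        (7.0, "valgus"), (3.0, "normal"),
        (5.0, "normal"),         # strict inequality at the boundary
        (5.0001, "valgus"), (0.0, "normal"), (30.0, "valgus"),
    ])
    def test_five_degree_rule(self, angle, label):
        assert kin.classify_foot_posture(angle) == label

    @pytest.mark.parametrize("bad", [-1.0, float("nan"), float("inf")])
    def test_invalid_angles_rejected(self, bad):
        with pytest.raises(kin.KinematicsError):
            kin.classify_foot_posture(bad)

    def test_monotone_in_angle(self):
        labels = [kin.classify_foot_posture(a) for a in np.linspace(0, 30, 61)]
        flips = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
        assert flips == 1 and labels[0] == "normal" and labels[-1] == "valgus"


class TestScaling:
    def test_identity_scaling_on_own_static_trial(self, model, participant,
                                                  quiet_spec):
        static = generate_static_trial(participant, model, quiet_spec, seed=5)
        scaled, report = kin.scale_model(model, static)
        for f in report.factors.values():
            assert f == pytest.approx(1.0, abs=1e-9)
        assert report.rms_error < 1e-6
        assert report.passed

    def test_recovers_ten_percent_longer_segments(self, model, participant,
                                                  quiet_spec):
        grown = rescale(model, {s: 1.1 for s in model.segments})
        static = generate_static_trial(participant, grown, quiet_spec, seed=5)
        _, report = kin.scale_model(model, static)
        for seg, f in report.factors.items():
            assert f == pytest.approx(1.1, abs=0.01), seg

    def test_noisy_static_trial_passes_study_gates(self, model, static_trial):
        _, report = kin.scale_model(model, static_trial)
        assert report.rms_error < 0.02
        assert report.max_error < 0.04
        assert report.passed

    def test_missing_marker_named_in_error(self, model, static_trial):
        markers = dict(static_trial.markers)
        markers.pop("HEEL")
        broken = type(static_trial)(
            participant_id="x", load_fraction=0.0, markers=markers,
            marker_rate=static_trial.marker_rate,
            grf_force=static_trial.grf_force, grf_cop=static_trial.grf_cop)
        with pytest.raises(kin.KinematicsError, match="HEEL"):
            kin.scale_model(model, broken)


class TestInverseKinematics:
    def test_zero_noise_recovery(self, model, quiet_trial):
        _, q = kin.inverse_kinematics(model, quiet_trial.markers,
                                      quiet_trial.marker_rate, prefiltered=True)
        err = np.degrees(np.sqrt(np.mean(
            (q[:, 3:] - quiet_trial.ground_truth.q[:, 3:]) ** 2)))
        assert err < 0.5

    def test_neutral_pose_gives_zero_angles(self, model):
        q0 = neutral_q(model)
        pos = marker_positions(model, q0)
        markers = {m: np.tile(p, (3, 1)) for m, p in pos.items()}
        _, q = kin.inverse_kinematics(model, markers, 100.0, prefiltered=True)
        np.testing.assert_allclose(np.degrees(q[:, 3:]), 0.0, atol=1e-3)

    def test_rigid_knee_rotation_recovered_exactly(self, model):
        """Rotating distal markers 10 degrees about the knee flexion axis
        must raise the recovered knee flexion by 10 degrees."""
        q0 = neutral_q(model)
        q1 = q0.copy()
        q1[3 + DOFS.index("knee_flexion")] = np.radians(10.0)
        markers = {}
        p0 = marker_positions(model, q0)
        p1 = marker_positions(model, q1)
        for name, (seg, _) in model.markers.items():
            src = p1[name] if seg in ("shank", "foot") else p0[name]
            markers[name] = np.tile(src, (2, 1))
        _, q = kin.inverse_kinematics(model, markers, 100.0, prefiltered=True)
        assert np.degrees(q[-1, 3 + DOFS.index("knee_flexion")]) == \
            pytest.approx(10.0, abs=0.1)

    def test_objective_non_increasing_over_iterations(self, model, rng):
        q_true = neutral_q(model)
        q_true[3:] += rng.normal(0, 0.3, 8)
        targets = marker_positions(model, q_true)
        q0 = neutral_q(model)
        _, history = kin.ik_frame(model, targets, q0)
        assert all(a >= b - 1e-15 for a, b in zip(history, history[1:]))


class TestSegmentation:
    def test_symmetric_triangle_deepest_at_mid(self):
        t = np.linspace(0, 4, 401)
        y = np.interp(t, [0, 2, 4], [0, 140, 0])
        seg = kin.segment_cycle(t, y)
        assert seg.deepest_index == 200

    def test_asymmetric_profile_maps_to_equal_halves(self):
        t = np.linspace(0, 4, 401)
        y = np.interp(t, [0, 3, 4], [0, 140, 0])     # slow down, fast up
        seg = kin.segment_cycle(t, y)
        assert (seg.deepest_index - seg.start_index) > (seg.end_index -
                                                        seg.deepest_index)
        curve = kin.time_normalize(t, y, seg)
        assert len(curve) == 101
        assert int(np.argmax(curve)) == 50

    def test_no_squat_detected_on_flat_series(self):
        t = np.linspace(0, 4, 100)
        with pytest.raises(kin.CycleError):
            kin.segment_cycle(t, np.full(100, 5.0))

    def test_tie_broken_to_earliest_frame(self):
        t = np.linspace(0, 4, 401)
        y = np.interp(t, [0, 1.5, 2.5, 4], [0, 140, 140, 0])
        seg = kin.segment_cycle(t, y)
        assert t[seg.deepest_index] == pytest.approx(1.5, abs=0.02)


class TestTimeNormalize:
    def test_output_length_101_and_extremum_at_50(self):
        t = np.linspace(0, 4, 401)
        y = np.interp(t, [0, 2, 4], [0, 140, 0])
        seg = kin.segment_cycle(t, y)
        curve = kin.time_normalize(t, y, seg)
        assert curve.shape == (101,)
        assert int(np.argmax(curve)) == 50
        assert curve[50] == pytest.approx(140.0)

    def test_identity_on_phase_grid(self):
        """A curve already sampled on the 101-point phase grid round-trips."""
        t = np.concatenate([np.linspace(0, 2, 51), np.linspace(2, 4, 51)[1:]])
        y = np.sin(np.linspace(0, np.pi, 101)) * 140
        seg = kin.PhaseSegmentation(0, 50, 100, t)
        out = kin.time_normalize(t, y, seg)
        np.testing.assert_allclose(out, y, atol=1e-9)

    def test_interpolation_never_overshoots(self, rng):
        t = np.linspace(0, 4, 401)
        y = np.interp(t, [0, 2, 4], [0, 140, 0]) + rng.normal(0, 2, 401)
        seg = kin.segment_cycle(t, y)
        curve = kin.time_normalize(t, y, seg)
        assert curve.max() <= y.max() + 1e-12
        assert curve.min() >= y.min() - 1e-12

    def test_out_of_range_segmentation_rejected(self):
        t = np.linspace(0, 1, 101)
        seg = kin.PhaseSegmentation(0, 50, 100, np.linspace(5, 6, 101))
        with pytest.raises(kin.KinematicsError):
            kin.time_normalize(t, np.zeros(101), seg)


class TestAngleMetrics:
    def _curves(self, **overrides):
        base = {d: np.zeros(101) for d in DOFS}
        base.update(overrides)
        return kin.CycleCurves("angles", "deg", base)

    def test_rom_of_known_range(self):
        c = self._curves(knee_flexion=np.linspace(10, 100, 101))
        assert kin.range_of_motion(c)["knee_sagittal_rom"] == pytest.approx(90.0)

    def test_rom_of_constant_curve_is_zero(self):
        assert kin.range_of_motion(self._curves())["hip_coronal_rom"] == 0.0

    def test_peaks_follow_anatomical_directions(self):
        hip_ab = -20.0 * np.sin(np.linspace(0, np.pi, 101))
        c = self._curves(hip_adduction=hip_ab,
                         knee_flexion=140 * np.sin(np.linspace(0, np.pi, 101)))
        peaks = kin.peak_angles(c)
        assert peaks["hip_abduction_peak"] == pytest.approx(20.0)
        assert peaks["knee_flexion_peak"] == pytest.approx(140.0)

    def test_cycle_curves_validate_length(self):
        with pytest.raises(kin.KinematicsError):
            kin.CycleCurves("bad", "deg", {"knee_flexion": np.zeros(77)})
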