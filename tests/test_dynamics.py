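"""Inverse dynamics: static equilibria, analytic oracles, recovery, invariance."""

import numpy as np
import pytest

from squatmech import kinematics as kin
from squatmech.dynamics import (DynamicsError, inverse_dynamics,
                                normalize_load, peak_moments)
from squatmech.model import (DOFS, GRAVITY, chain_state, neutral_q, rescale,
                             segment_com)


def _static_series(q, n=60):
    return np.tile(q, (n, 1))


def _grf_static(model, n):
    routed = (model.weight_share * model.segments["pelvis"].mass
              + sum(model.segments[s].mass for s in ("thigh", "shank", "foot")))
    force = np.zeros((n, 3))
    force[:, 1] = routed * GRAVITY
    return force


class TestStaticEquilibria:
    def test_upright_stance_with_grf_through_line_of_action_zeroes_moments(
            self, model):
        """Quiet standing with the COP under the supported centre of mass
        (joint centres are vertically aligned; only the foot COM sits a few
        cm anterior) leaves every joint moment within the 0.5 N m slack."""
        q = neutral_q(model)
        n = 60
        qs = _static_series(q, n)
        force = _grf_static(model, n)
        st = chain_state(model, q)
        routed_upper = model.weight_share * model.segments["pelvis"].mass
        masses = {"thigh": st.p_hip, "shank": st.p_knee}
        x_num = routed_upper * st.p_hip[0]
        m_tot = routed_upper
        for seg in ("thigh", "shank", "foot"):
            com = segment_com(model, st, seg)
            x_num += model.segments[seg].mass * com[0]
            m_tot += model.segments[seg].mass
        cop = np.zeros((n, 3))
        cop[:, 0] = x_num / m_tot
        cop[:, 2] = st.p_ankle[2]
        idr = inverse_dynamics(model, qs, 100.0, force, cop)
        for d in ("hip_flexion", "knee_flexion", "hip_adduction",
                  "ankle_dorsiflexion"):
            assert np.all(np.abs(idr.torques[d][5:-5]) < 0.5), d

    def test_pendulum_hand_value(self, model):
        """Shank held horizontal, 4 kg at 0.2 m from the knee: 7.848 N m."""
        pend = rescale(model, {})
        pend.segments["shank"].mass = 4.0
        pend.segments["shank"].com_offset = 0.2 / pend.segments["shank"].length
        pend.segments["shank"].inertia = np.full(3, 1e-12)
        pend.segments["foot"].mass = 1e-12
        pend.segments["foot"].inertia = np.full(3, 1e-12)
        q = neutral_q(pend)
        q[3 + DOFS.index("knee_flexion")] = np.radians(90.0)  # shank horizontal
        n = 40
        idr = inverse_dynamics(pend, _static_series(q, n), 100.0,
                               np.zeros((n, 3)), np.zeros((n, 3)))
        tau = idr.torques["knee_flexion"][n // 2]
        assert abs(tau) == pytest.approx(4.0 * GRAVITY * 0.2, rel=1e-9)
        assert tau == pytest.approx(7.848, abs=1e-3)

    def test_quasi_static_matches_lever_arm_oracle(self, model):
        """Static deep pose: knee moment equals the hand lever-arm balance."""
        q = neutral_q(model)
        q[3 + DOFS.index("hip_flexion")] = np.radians(100.0)
        q[3 + DOFS.index("knee_flexion")] = np.radians(134.0)
        q[3 + DOFS.index("ankle_dorsiflexion")] = np.radians(34.0)
        n = 60
        force = _grf_static(model, n)
        st = chain_state(model, q)
        cop = np.zeros((n, 3))
        cop[:, 0] = st.p_ankle[0] + 0.1
        cop[:, 2] = st.p_ankle[2]
        idr = inverse_dynamics(model, _static_series(q, n), 100.0, force, cop)

        g_vec = np.array([0.0, -GRAVITY, 0.0])
        m_ext = np.cross(cop[0] - st.p_knee, force[0])
        for seg in ("shank", "foot"):
            com = segment_com(model, st, seg)
            m_ext = m_ext + np.cross(com - st.p_knee,
                                     model.segments[seg].mass * g_vec)
        hand = -(m_ext @ st.axes["knee_flexion"])
        assert idr.torques["knee_flexion"][n // 2] == pytest.approx(hand, abs=1e-6)

    def test_translation_invariance(self, model, quiet_trial):
        """Shifting the lab origin leaves every joint moment unchanged."""
        gt = quiet_trial.ground_truth
        shift = np.array([1.3, 0.0, -2.1])
        q2 = gt.q.copy()
        q2[:, 0:3] += shift
        idr1 = inverse_dynamics(model, gt.q, 100.0, gt.grf_force, gt.grf_cop)
        idr2 = inverse_dynamics(model, q2, 100.0, gt.grf_force,
                                gt.grf_cop + shift)
        for d in DOFS:
            np.testing.assert_allclose(idr2.torques[d], idr1.torques[d],
                                       atol=1e-9)


class TestRoundTrip:
    def test_torque_recovery_on_zero_noise_trial(self, model, quiet_trial):
        gt = quiet_trial.ground_truth
        _, q = kin.inverse_kinematics(model, quiet_trial.markers, 100.0,
                                      prefiltered=True)
        idr = inverse_dynamics(model, q, 100.0, quiet_trial.grf_force,
                               quiet_trial.grf_cop)
        truth = np.column_stack([gt.torques[d] for d in DOFS])
        est = np.column_stack([idr.torques[d] for d in DOFS])
        rel = np.sqrt(np.mean((est - truth) ** 2)) / np.sqrt(np.mean(truth**2))
        assert rel < 0.02

    def test_graceful_degradation_with_noise(self, model, quiet_trial,
                                             noisy_trial):
        """Marker noise worsens recovery but stays within a usable bound."""
        def rel_err(trial):
            gt = trial.ground_truth
            markers = kin.filter_markers(trial.markers, 100.0)
            _, q = kin.inverse_kinematics(model, markers, 100.0, prefiltered=True)
            q = kin.lowpass(q, 100.0, 6.0)
            idr = inverse_dynamics(model, q, 100.0, gt.grf_force, gt.grf_cop)
            truth = np.column_stack([gt.torques[d] for d in DOFS])
            est = np.column_stack([idr.torques[d] for d in DOFS])
            return np.sqrt(np.mean((est - truth) ** 2)) / np.sqrt(np.mean(truth**2))

        clean, noisy = rel_err(quiet_trial), rel_err(noisy_trial)
        assert clean < 0.02
        assert clean <= noisy < 0.25

    def test_rate_mismatch_rejected(self, model, quiet_trial):
        with pytest.raises(DynamicsError):
            inverse_dynamics(model, quiet_trial.ground_truth.q, 100.0,
                             quiet_trial.grf_force[:-5], quiet_trial.grf_cop)


class TestNormalizeLoad:
    def test_stated_rule_arithmetic(self):
        assert normalize_load(102.0, 65.0, 20.0) == pytest.approx(1.2)

    def test_zero_barbell_divides_by_body_mass(self):
        assert normalize_load(130.0, 65.0, 0.0) == pytest.approx(2.0)

    def test_scale_invariance(self):
        assert normalize_load(100.0, 50.0, 10.0) == pytest.approx(
            normalize_load(200.0, 100.0, 20.0))

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(DynamicsError):
            normalize_load(10.0, 0.0, 5.0)


class TestPeakMoments:
    def _curves(self, **overrides):
        base = {d: np.zeros(101) for d in DOFS}
        base.update(overrides)
        return kin.CycleCurves("moments", "N m/kg", base)

    def test_constant_curve(self):
        c = self._curves(knee_adduction=np.full(101, -0.5))
        # external adduction peak = max of the negated internal curve
        assert peak_moments(c)["knee_adduction_moment"] == pytest.approx(0.5)

    def test_sinusoid_selects_convention_extremum(self):
        s = 0.3 * np.sin(np.linspace(0, 2 * np.pi, 101))
        c = self._curves(knee_flexion=s, ankle_dorsiflexion=s)
        peaks = peak_moments(c)
        assert peaks["knee_flexion_moment"] == pytest.approx(-0.3, abs=1e-6)
        # plantarflexion row is reported as a magnitude
        assert peaks["ankle_extension_moment"] == pytest.approx(0.3, abs=1e-6)

    def test_extensor_dominated_squat_signs(self, model, quiet_trial):
        gt = quiet_trial.ground_truth
        t = np.arange(len(gt.q)) / 100.0
        seg = kin.segment_cycle(t, np.degrees(gt.q[:, 6]))
        msys = 65.67
        curves = kin.normalize_all(
            t, {d: gt.torques[d] / msys for d in DOFS}, seg, "m", "N m/kg")
        peaks = peak_moments(curves)
        assert peaks["knee_flexion_moment"] < -0.5     # net extensor
        assert peaks["hip_flexion_moment"] < -0.5      # net extensor
        assert peaks["knee_adduction_moment"] > 0.0    # medial loading
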