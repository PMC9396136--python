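"""Static optimization and EMG processing."""

import numpy as np
import pytest

from squatmech import kinematics as kin
from squatmech.model import MuscleElement, rescale
from squatmech.neuromuscular import (EmgError, OptimizationError,
                                     emg_bandpass, emg_rms_envelope,
                                     normalize_mvc, static_optimization,
                                     validate_activations)


def _toy_model(model, muscles):
    """Copy of the model whose only acting muscles are the given ones.

    Fresh inert copies of the EMG-monitored muscles keep the model valid
    without touching the session fixture's muscle objects.
    """
    toy = rescale(model, {})
    keep = {m: MuscleElement(m, model.muscles[m].fmax, {})
            for m in ("rectus_femoris", "biceps_femoris",
                      "tibialis_anterior", "gastrocnemius")}
    toy.muscles = {**keep, **muscles}
    return toy


class TestStaticOptimization:
    def test_two_identical_muscles_split_evenly(self, model):
        toy = _toy_model(model, {
            "a": MuscleElement("a", 1000.0, {"knee_flexion": (0.05,)}),
            "b": MuscleElement("b", 1000.0, {"knee_flexion": (0.05,)}),
        })
        sol = static_optimization(
            toy, {"knee_flexion": np.array([50.0])},
            {d: np.zeros(1) for d in toy.muscles["a"].arms},
            so_dofs=("knee_flexion",), enable_reserves=False)
        assert sol.activations["a"][0] == pytest.approx(0.5, abs=1e-9)
        assert sol.activations["b"][0] == pytest.approx(0.5, abs=1e-9)

    def test_kkt_closed_form_hand_case(self, model):
        """arms (0.05, 0.025) m, Fmax 1000 N each, M = 50 N m -> a = (0.8, 0.4)."""
        toy = _toy_model(model, {
            "a": MuscleElement("a", 1000.0, {"knee_flexion": (0.05,)}),
            "b": MuscleElement("b", 1000.0, {"knee_flexion": (0.025,)}),
        })
        sol = static_optimization(
            toy, {"knee_flexion": np.array([50.0])}, {"knee_flexion": np.zeros(1)},
            so_dofs=("knee_flexion",), enable_reserves=False)
        a, b = sol.activations["a"][0], sol.activations["b"][0]
        assert a == pytest.approx(0.8, rel=1e-9)
        assert b == pytest.approx(0.4, rel=1e-9)
        # the balance itself: 50*0.8 + 25*0.4 = 50
        assert 50.0 * a + 25.0 * b == pytest.approx(50.0, abs=1e-9)

    def test_zero_moment_gives_zero_activation(self, model):
        sol = static_optimization(
            model, {d: np.zeros(3) for d in sol_dofs(model)},
            {d: np.zeros(3) for d in sol_dofs(model)})
        for m, a in sol.activations.items():
            np.testing.assert_allclose(a, 0.0, atol=1e-9)

    def test_infeasible_without_reserves_names_dof(self, model):
        toy = _toy_model(model, {
            "a": MuscleElement("a", 100.0, {"knee_flexion": (0.05,)}),
        })
        with pytest.raises(OptimizationError, match="knee_flexion"):
            static_optimization(
                toy, {"knee_flexion": np.array([500.0])},
                {"knee_flexion": np.zeros(1)},
                so_dofs=("knee_flexion",), enable_reserves=False)

    def test_reserves_absorb_deficit_with_bounded_activations(self, model):
        toy = _toy_model(model, {
            "a": MuscleElement("a", 100.0, {"knee_flexion": (0.05,)}),
        })
        sol = static_optimization(
            toy, {"knee_flexion": np.array([500.0])},
            {"knee_flexion": np.zeros(1)}, so_dofs=("knee_flexion",))
        assert sol.activations["a"][0] <= 1.0 + 1e-12
        total = (0.05 * 100.0 * sol.activations["a"][0]
                 + sol.reserves["knee_flexion"][0])
        assert total == pytest.approx(500.0, abs=1e-6)

    def test_fmax_homogeneity(self, model):
        """Scaling every Fmax by k scales activations by 1/k, forces unchanged."""
        def solve(scale):
            toy = _toy_model(model, {
                "a": MuscleElement("a", 1000.0 * scale, {"knee_flexion": (0.05,)}),
                "b": MuscleElement("b", 1000.0 * scale, {"knee_flexion": (0.025,)}),
            })
            return static_optimization(
                toy, {"knee_flexion": np.array([30.0])},
                {"knee_flexion": np.zeros(1)},
                so_dofs=("knee_flexion",), enable_reserves=False)

        s1, s2 = solve(1.0), solve(2.0)
        for m in ("a", "b"):
            assert s2.activations[m][0] == pytest.approx(
                s1.activations[m][0] / 2.0, rel=1e-6)
            assert s2.forces[m][0] == pytest.approx(s1.forces[m][0], rel=1e-6)

    def test_moment_balance_residual_tiny_on_squat_trial(self, model,
                                                         quiet_trial):
        gt = quiet_trial.ground_truth
        poses = {d: np.degrees(gt.q[:, 3 + i])
                 for i, d in enumerate(sol_dofs(model, all_dofs=True))}
        sol = static_optimization(model, gt.torques, poses)
        for d in sol.dofs:
            assert np.max(np.abs(sol.residual[d])) < 1e-6
        for m, a in sol.activations.items():
            assert np.all((a >= -1e-12) & (a <= 1.0 + 1e-12))


def sol_dofs(model, all_dofs=False):
    from squatmech.model import DOFS
    from squatmech.neuromuscular import DEFAULT_SO_DOFS
    return DOFS if all_dofs else DEFAULT_SO_DOFS


class TestEmgFilter:
    def test_50hz_attenuated_over_40db(self):
        rate, t = 1000.0, np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 50.0 * t)
        y = emg_bandpass(x, rate)
        gain = np.std(y[500:-500]) / np.std(x[500:-500])
        assert 20 * np.log10(gain) < -40.0

    def test_200hz_passed_within_1db(self):
        rate, t = 1000.0, np.arange(4000) / 1000.0
        x = np.sin(2 * np.pi * 200.0 * t)
        y = emg_bandpass(x, rate)
        gain = np.std(y[500:-500]) / np.std(x[500:-500])
        assert abs(20 * np.log10(gain)) < 1.0

    def test_zero_signal_maps_to_zero(self):
        np.testing.assert_allclose(emg_bandpass(np.zeros(2000), 1000.0), 0.0,
                                   atol=1e-12)

    def test_strict_mode_rejects_band_at_nyquist(self):
        with pytest.raises(EmgError):
            emg_bandpass(np.zeros(2000), 1000.0, strict=True)

    def test_band_below_nyquist_is_true_bandpass(self):
        rate, t = 2000.0, np.arange(8000) / 2000.0
        x = np.sin(2 * np.pi * 700.0 * t)      # above the 500 Hz edge
        y = emg_bandpass(x, rate)
        assert np.std(y[500:-500]) < 0.05 * np.std(x)


class TestEnvelopeAndMvc:
    def test_constant_signal_rms_equals_amplitude(self):
        _, rms = emg_rms_envelope(np.full(2000, 0.3), 1000.0)
        np.testing.assert_allclose(rms, 0.3, atol=1e-12)

    def test_envelope_monotone_in_signal_magnitude(self, rng):
        x = rng.normal(0, 1, 2000)
        _, r1 = emg_rms_envelope(x, 1000.0)
        _, r2 = emg_rms_envelope(2 * x, 1000.0)
        assert np.all(r2 >= r1 - 1e-12)

    def test_mvc_normalization_endpoints(self):
        t = np.arange(10.0)
        env = normalize_mvc(t, np.full(10, 2.0), 2.0)
        np.testing.assert_allclose(env.values, 1.0)       # test RMS == MVC RMS
        env0 = normalize_mvc(t, np.zeros(10), 2.0)
        np.testing.assert_allclose(env0.values, 0.0)      # silent muscle

    def test_values_clamped_to_unit_interval(self):
        env = normalize_mvc(np.arange(3.0), np.array([0.5, 2.0, 5.0]), 2.0)
        assert env.values.max() <= 1.0

    def test_nonpositive_mvc_rejected(self):
        with pytest.raises(EmgError):
            normalize_mvc(np.arange(3.0), np.ones(3), 0.0)


class TestValidation:
    def _curves(self, data):
        return kin.CycleCurves("c", "activation", data)

    def test_identical_curves_perfect_agreement(self):
        x = np.linspace(0, 1, 101)
        rep = validate_activations(self._curves({"m": x}), self._curves({"m": x}))
        assert rep.loc["m", "r"] == pytest.approx(1.0)
        assert rep.loc["m", "rmse"] == pytest.approx(0.0)
        assert bool(rep.loc["m", "passed"])

    def test_negated_curve_gives_minus_one(self):
        x = np.sin(np.linspace(0, np.pi, 101))
        rep = validate_activations(self._curves({"m": x}),
                                   self._curves({"m": -x}))
        assert rep.loc["m", "r"] == pytest.approx(-1.0)
        assert not bool(rep.loc["m", "passed"])

    def test_constant_series_reported_not_nan(self):
        x = np.linspace(0, 1, 101)
        rep = validate_activations(self._curves({"m": np.full(101, 0.4)}),
                                   self._curves({"m": x}))
        assert rep.loc["m", "r"] is None
        assert "undefined" in rep.loc["m", "note"]

    def test_synthetic_trial_emg_matches_static_optimization(
            self, model, participant, quiet_trial):
        """EMG envelopes built from the generating activations agree with the
        pipeline's static-optimization activations (r >= 0.9 per muscle)."""
        from squatmech.pipeline import analyze_trial
        res = analyze_trial(model, quiet_trial, participant.mass, 0.0)
        assert res.validation is not None
        for muscle, row in res.validation.iterrows():
            assert row["r"] is not None and row["r"] >= 0.9, muscle
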