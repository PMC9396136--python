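"""Model scaling, marker-driven inverse kinematics and squat-cycle geometry.

Per frame, inverse kinematics finds the generalized coordinates minimizing
the sum of squared distances between experimental markers and the model's
virtual markers (damped Gauss-Newton / Levenberg-Marquardt with an analytic
geometric Jacobian, warm-started from the previous frame).  The squat cycle
is segmented from the knee-flexion trace (upright -> deepest -> upright) and
every quantity is resampled to a 101-point 0-100% cycle in which the descent
occupies samples 0-50 and the ascent samples 51-100.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt

from .model import (COORDS, DOFS, BodyModel, chain_state, marker_positions,
                    neutral_q, rescale)

N_CYCLE = 101  # field-standard cycle grid


class KinematicsError(ValueError):
    pass


class IKError(RuntimeError):
    pass


class CycleError(ValueError):
    """Raised when no squat can be detected in a knee-flexion trace."""


# ---------------------------------------------------------------------------
# group classification and filtering
# ---------------------------------------------------------------------------


def classify_foot_posture(static_valgus_angle: float) -> str:
    """Classify standing rearfoot posture by the 5-degree rule.

    Strictly greater than 5 degrees of static rearfoot valgus -> ``"valgus"``;
    otherwise ``"normal"`` (the boundary value itself is normal).
    """
    a = float(static_valgus_angle)
    if not math.isfinite(a) or a < 0:
        raise KinematicsError(f"valgus angle must be finite and >= 0, got {a!r}")
    return "valgus" if a > 5.0 else "normal"


def lowpass(x: np.ndarray, rate: float, cutoff: float = 6.0) -> np.ndarray:
    """Zero-lag 4th-order Butterworth low-pass (2nd order, forward-backward)."""
    b, a = butter(2, cutoff / (rate / 2.0))
    return filtfilt(b, a, x, axis=0)


def filter_markers(markers: dict[str, np.ndarray], rate: float,
                   cutoff: float = 6.0) -> dict[str, np.ndarray]:
    return {k: lowpass(v, rate, cutoff) for k, v in markers.items()}


# ---------------------------------------------------------------------------
# scaling
# ---------------------------------------------------------------------------


@dataclass
class ScalingReport:
    factors: dict[str, float]
    rms_error: float   # m, over all markers and frames
    max_error: float   # m, worst single marker distance
    rms_gate: float = 0.02
    max_gate: float = 0.04

    @property
    def passed(self) -> bool:
        return self.rms_error < self.rms_gate and self.max_error < self.max_gate


def scale_model(model: BodyModel, static_trial) -> tuple[BodyModel, ScalingReport]:
    """Scale segment geometry to a static standing trial and report residuals.

    Per-segment scale factors are ratios of experimental to model
    inter-marker distances (marker offsets are defined proportional to their
    segment, so intra-segment distances carry the scale).  The report's
    residuals come from running inverse kinematics on the scaled model over
    the static trial.
    """
    missing = [m for m in model.marker_names() if m not in static_trial.markers]
    if missing:
        raise KinematicsError(f"static trial is missing marker(s): {', '.join(missing)}")

    mean_pos = {m: np.asarray(static_trial.markers[m]).mean(axis=0)
                for m in model.marker_names()}
    by_seg: dict[str, list[str]] = {}
    for name, (seg, _) in model.markers.items():
        by_seg.setdefault(seg, []).append(name)

    factors = {}
    for seg, names in by_seg.items():
        ratios = []
        for a, b in itertools.combinations(names, 2):
            d_model = np.linalg.norm(model.markers[a][1] - model.markers[b][1])
            if d_model < 1e-9:
                continue
            d_exp = np.linalg.norm(mean_pos[a] - mean_pos[b])
            ratios.append(d_exp / d_model)
        factors[seg] = float(np.mean(ratios)) if ratios else 1.0

    scaled = rescale(model, factors)

    _, q = inverse_kinematics(scaled, static_trial.markers, static_trial.marker_rate,
                              prefiltered=True)
    sq_sum, count, worst = 0.0, 0, 0.0
    for i in range(q.shape[0]):
        virtual = marker_positions(scaled, q[i])
        for m in scaled.marker_names():
            d = float(np.linalg.norm(virtual[m] - static_trial.markers[m][i]))
            sq_sum += d * d
            count += 1
            worst = max(worst, d)
    report = ScalingReport(factors, math.sqrt(sq_sum / count), worst)
    return scaled, report


# ---------------------------------------------------------------------------
# inverse kinematics
# ---------------------------------------------------------------------------

#: rotational DOFs that move each segment's markers
_SEG_DOFS = {
    "pelvis": (),
    "thigh": ("hip_flexion", "hip_adduction", "hip_rotation"),
    "shank": ("hip_flexion", "hip_adduction", "hip_rotation",
              "knee_flexion", "knee_adduction", "knee_rotation"),
    "foot": DOFS,
}


class _IKWorkspace:
    """Vectorized residual/Jacobian assembly for a fixed marker set."""

    _SEG_IDX = {"pelvis": 0, "thigh": 1, "shank": 2, "foot": 3}

    def __init__(self, model: BodyModel, names: list[str]):
        self.model = model
        self.names = names
        self.seg_idx = np.array([self._SEG_IDX[model.markers[m][0]] for m in names])
        self.offs = np.array([model.markers[m][1] for m in names])
        # mask[m, d]: rotational DOF d moves marker m's segment
        mask = np.zeros((len(names), len(DOFS)), dtype=bool)
        for k, m in enumerate(names):
            seg = model.markers[m][0]
            for d in _SEG_DOFS[seg]:
                mask[k, DOFS.index(d)] = True
        self.mask = mask
        self.nm = len(names)
        self.jac_t = np.tile(np.eye(3), (self.nm, 1))   # translation block

    def residual_jacobian(self, q: np.ndarray, targets: np.ndarray):
        """targets is (nm, 3); returns flattened residual and (3nm, 11) Jacobian."""
        st = chain_state(self.model, q)
        origins = np.stack([st.p_pelvis, st.p_hip, st.p_knee, st.p_ankle])
        rots = np.stack([st.r_pelvis, st.r_thigh, st.r_shank, st.r_foot])
        p = origins[self.seg_idx] + np.einsum(
            "mij,mj->mi", rots[self.seg_idx], self.offs)
        r = (p - targets).ravel()
        axes = np.stack([st.axes[d] for d in DOFS])          # (8, 3)
        jpos = np.stack([st.joint_of[d] for d in DOFS])      # (8, 3)
        diff = p[:, None, :] - jpos[None, :, :]              # (nm, 8, 3)
        cols = np.cross(axes[None, :, :], diff)              # (nm, 8, 3)
        cols *= self.mask[:, :, None]
        jac = np.empty((3 * self.nm, len(COORDS)))
        jac[:, 0:3] = self.jac_t
        jac[:, 3:] = cols.transpose(0, 2, 1).reshape(3 * self.nm, len(DOFS))
        return r, jac


def _ik_residual_jacobian(model: BodyModel, q: np.ndarray, targets: dict[str, np.ndarray]):
    names = list(targets)
    ws = _IKWorkspace(model, names)
    tgt = np.array([targets[m] for m in names])
    return ws.residual_jacobian(q, tgt)


def ik_frame(model: BodyModel, targets: dict[str, np.ndarray], q0: np.ndarray,
             tol: float = 1e-8, max_iter: int = 200):
    """Solve one frame by Levenberg-Marquardt; returns (q, cost_history).

    The history contains the objective value at every accepted iterate, so it
    is non-increasing by construction (steps that would increase the
    objective are rejected and retried with stronger damping).
    """
    names = list(targets)
    ws = _IKWorkspace(model, names)
    tgt = np.array([targets[m] for m in names])
    return _ik_frame_ws(ws, tgt, q0, tol, max_iter)


def _ik_frame_ws(ws: "_IKWorkspace", targets: np.ndarray, q0: np.ndarray,
                 tol: float = 1e-8, max_iter: int = 200):
    q = q0.copy()
    r, jac = ws.residual_jacobian(q, targets)
    cost = float(r @ r)
    history = [cost]
    lam = 1e-6
    for _ in range(max_iter):
        g = jac.T @ r
        h = jac.T @ jac
        accepted = False
        for _ in range(12):
            try:
                step = np.linalg.solve(h + lam * np.eye(h.shape[0]), -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            q_new = q + step
            r_new, jac_new = ws.residual_jacobian(q_new, targets)
            cost_new = float(r_new @ r_new)
            if cost_new <= cost:
                q, r, jac, cost = q_new, r_new, jac_new, cost_new
                lam = max(lam / 3.0, 1e-10)
                accepted = True
                break
            lam *= 10.0
        history.append(cost)
        if not accepted or history[-2] - history[-1] < tol:
            break
    else:
        raise IKError("inverse kinematics did not converge")
    return q, history


def inverse_kinematics(model: BodyModel, markers: dict[str, np.ndarray],
                       rate: float, q0: np.ndarray | None = None,
                       prefiltered: bool = False):
    """Per-frame IK over a whole trial.

    Returns ``(time, q)`` where ``q`` is (n_frames, 11) generalized
    coordinates: pelvis translation in metres then the 8 DOF angles in
    radians.  Use :func:`angles_deg` for the degree-valued DOF series.
    Markers are expected already low-pass filtered (`prefiltered=True`
    documents that the caller did, or does not want, filtering).
    """
    if not model.scaled:
        # an unscaled model is permitted but the caller should know
        pass
    names = [m for m in model.marker_names() if m in markers]
    if not names:
        raise KinematicsError("no model markers present in the trial")
    n = len(markers[names[0]])
    q = np.zeros((n, len(COORDS)))
    guess = q0.copy() if q0 is not None else _initial_guess(model, markers, names)
    ws = _IKWorkspace(model, names)
    stacked = np.stack([np.asarray(markers[m], dtype=float) for m in names], axis=1)
    for i in range(n):
        try:
            guess, _ = _ik_frame_ws(ws, stacked[i], guess)
        except IKError as exc:
            raise IKError(f"IK failed at frame {i}: {exc}") from exc
        q[i] = guess
    time = np.arange(n) / rate
    return time, q


def _initial_guess(model: BodyModel, markers, names) -> np.ndarray:
    q = neutral_q(model)
    pelvis = [m for m in names if model.markers[m][0] == "pelvis"]
    if pelvis:
        exp = np.mean([markers[m][0] for m in pelvis], axis=0)
        loc = np.mean([model.markers[m][1] for m in pelvis], axis=0)
        q[0:3] = exp - loc
    return q


def angles_deg(q: np.ndarray) -> dict[str, np.ndarray]:
    """DOF angle series of an IK solution, degrees, keyed by DOF name."""
    return {d: np.degrees(q[:, 3 + i]) for i, d in enumerate(DOFS)}


# ---------------------------------------------------------------------------
# cycle segmentation and time normalization
# ---------------------------------------------------------------------------


@dataclass
class PhaseSegmentation:
    """Raw-time indices of a squat cycle: upright -> deepest -> upright."""

    start_index: int
    deepest_index: int
    end_index: int
    time: np.ndarray

    @property
    def t_start(self) -> float:
        return float(self.time[self.start_index])

    @property
    def t_deepest(self) -> float:
        return float(self.time[self.deepest_index])

    @property
    def t_end(self) -> float:
        return float(self.time[self.end_index])


def segment_cycle(time: np.ndarray, knee_flexion_deg: np.ndarray,
                  upright_threshold: float = 10.0) -> PhaseSegmentation:
    """Locate the squat cycle in a knee-flexion trace.

    The deepest point is the global flexion maximum (earliest frame on
    ties); the cycle starts at the last upright-threshold crossing before
    it and ends at the first one after it.
    """
    y = np.asarray(knee_flexion_deg, dtype=float)
    deepest = int(np.argmax(y))
    if y[deepest] <= upright_threshold:
        raise CycleError("no squat detected: knee flexion never exceeds "
                         f"{upright_threshold:g} degrees")
    before = np.nonzero(y[:deepest] <= upright_threshold)[0]
    after = np.nonzero(y[deepest:] <= upright_threshold)[0]
    start = int(before[-1]) if len(before) else 0
    end = int(deepest + after[0]) if len(after) else len(y) - 1
    return PhaseSegmentation(start, deepest, end, np.asarray(time, dtype=float))


@dataclass
class CycleCurves:
    """A quantity resampled to the 101-point squat cycle, per DOF/channel."""

    name: str
    units: str
    curves: dict[str, np.ndarray]

    def __post_init__(self):
        for key, vals in self.curves.items():
            vals = np.asarray(vals, dtype=float)
            if vals.shape != (N_CYCLE,):
                raise KinematicsError(f"{self.name}/{key}: expected {N_CYCLE} samples")
            if not np.all(np.isfinite(vals)):
                raise KinematicsError(f"{self.name}/{key}: non-finite samples")
            self.curves[key] = vals

    def __getitem__(self, key: str) -> np.ndarray:
        return self.curves[key]


def time_normalize(time: np.ndarray, values: np.ndarray,
                   seg: PhaseSegmentation) -> np.ndarray:
    """Resample one channel onto the 101-point cycle grid.

    Descent (start -> deepest) maps to samples 0-50 and ascent
    (deepest -> end) to samples 51-100 by piecewise-linear interpolation, so
    sample 50 is exactly the value at the deepest frame regardless of how
    asymmetric the two phases are in raw time.
    """
    time = np.asarray(time, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (seg.t_start < seg.t_deepest < seg.t_end):
        raise KinematicsError("degenerate segmentation (phases must be ordered)")
    # the series may live on its own time base (e.g. EMG envelopes); allow
    # up to one sample spacing of slack at either end before calling it
    # out of bounds
    slack = (time[-1] - time[0]) / max(len(time) - 1, 1)
    if seg.t_start < time[0] - slack or seg.t_end > time[-1] + slack:
        raise KinematicsError("segmentation lies outside the series time range")
    t_desc = np.linspace(seg.t_start, seg.t_deepest, 51)
    t_asc = np.linspace(seg.t_deepest, seg.t_end, 51)[1:]
    out = np.empty(N_CYCLE)
    out[:51] = np.interp(t_desc, time, values)
    out[51:] = np.interp(t_asc, time, values)
    return out


def normalize_all(time: np.ndarray, series: dict[str, np.ndarray],
                  seg: PhaseSegmentation, name: str, units: str) -> CycleCurves:
    return CycleCurves(name, units,
                       {k: time_normalize(time, v, seg) for k, v in series.items()})


# ---------------------------------------------------------------------------
# discrete angle metrics
# ---------------------------------------------------------------------------

#: joint/plane -> DOF providing that plane's angle
PLANES = {
    ("hip", "sagittal"): "hip_flexion",
    ("hip", "coronal"): "hip_adduction",
    ("hip", "transverse"): "hip_rotation",
    ("knee", "sagittal"): "knee_flexion",
    ("knee", "coronal"): "knee_adduction",
    ("knee", "transverse"): "knee_rotation",
    ("ankle", "sagittal"): "ankle_dorsiflexion",
    ("ankle", "coronal"): "subtalar_supination",
}


def peak_angles(curves: CycleCurves) -> dict[str, float]:
    """Peak joint angles in the anatomical directions of the result tables.

    Each value is the magnitude of the convention-signed extremum in the
    named direction (e.g. hip abduction is the most negative hip frontal
    angle, reported positive).
    """
    c = curves.curves
    return {
        "hip_flexion_peak": float(np.max(c["hip_flexion"])),
        "hip_abduction_peak": float(-np.min(c["hip_adduction"])),
        "knee_flexion_peak": float(np.max(c["knee_flexion"])),
        "knee_adduction_peak": float(np.max(c["knee_adduction"])),
        "knee_abduction_peak": float(-np.min(c["knee_adduction"])),
        "ankle_dorsiflexion_peak": float(np.max(c["ankle_dorsiflexion"])),
        "foot_valgus_peak": float(-np.min(c["subtalar_supination"])),
    }


def range_of_motion(curves: CycleCurves) -> dict[str, float]:
    """Per-joint, per-plane range of motion (max minus min), degrees."""
    out = {}
    for (joint, plane), dof in PLANES.items():
        vals = curves[dof]
        out[f"{joint}_{plane}_rom"] = float(np.max(vals) - np.min(vals))
    return out
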