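"""Net joint moments by bottom-up recursive Newton-Euler inverse dynamics.

The recursion runs foot -> shank -> thigh.  The foot carries the ground
reaction force at its centre of pressure; each joint then receives the
negated proximal wrench of the segment below.  Segment kinematics (COM
acceleration, angular velocity/acceleration) are numerically differentiated
with central differences (one-sided at the endpoints); the caller decides
what filtering the coordinates received beforehand.  Joint moments are
projected onto the model's DOF axes, so the reported torques are exactly
the generalized forces conjugate to the joint angles, signed by the fixed
convention (e.g. a net knee extensor moment is negative on the flexion DOF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import DOFS, GRAVITY, BodyModel, chain_state, segment_com

_G = np.array([0.0, -GRAVITY, 0.0])


class DynamicsError(ValueError):
    pass


def central_diff(x: np.ndarray, dt: float) -> np.ndarray:
    """First derivative along axis 0; central inside, one-sided at the ends."""
    return np.gradient(x, dt, axis=0)


def _omega_from_rotations(r: np.ndarray, dt: float) -> np.ndarray:
    """World-frame angular velocity from a (n, 3, 3) rotation series."""
    rdot = np.gradient(r, dt, axis=0)
    skew = np.einsum("nij,nkj->nik", rdot, r)  # Rdot R^T
    omega = np.empty((r.shape[0], 3))
    omega[:, 0] = 0.5 * (skew[:, 2, 1] - skew[:, 1, 2])
    omega[:, 1] = 0.5 * (skew[:, 0, 2] - skew[:, 2, 0])
    omega[:, 2] = 0.5 * (skew[:, 1, 0] - skew[:, 0, 1])
    return omega


@dataclass
class IDResult:
    """Inverse-dynamics output for one trial (raw N and N m)."""

    time: np.ndarray
    torques: dict[str, np.ndarray]       # DOF -> (n,)
    f_hip: np.ndarray                    # force on thigh at the hip, world frame
    f_knee: np.ndarray                   # force on shank at the knee
    f_ankle: np.ndarray                  # force on foot at the ankle
    m_knee: np.ndarray                   # knee moment vector, world frame
    axes: dict[str, np.ndarray]          # DOF -> (n, 3) world axes
    shank_axis: np.ndarray               # (n, 3) unit tibia long axis (ankle->knee)
    p_knee: np.ndarray                   # (n, 3) knee centre


def inverse_dynamics(model: BodyModel, q: np.ndarray, rate: float,
                     grf_force: np.ndarray, grf_cop: np.ndarray) -> IDResult:
    """Compute ankle, knee and hip net moments for a coordinate time series.

    ``q`` is (n, 11): pelvis translation (m) + 8 DOF angles (radians).
    ``grf_force``/``grf_cop`` must be sampled on the same time base.
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    if len(grf_force) != n or len(grf_cop) != n:
        raise DynamicsError(
            f"stream rate mismatch: {n} coordinate frames vs "
            f"{len(grf_force)} GRF samples")
    dt = 1.0 / rate

    segs = ("thigh", "shank", "foot")
    coms = {s: np.empty((n, 3)) for s in segs}
    rots = {s: np.empty((n, 3, 3)) for s in segs}
    p_knee = np.empty((n, 3))
    p_ankle = np.empty((n, 3))
    p_hip = np.empty((n, 3))
    axes = {d: np.empty((n, 3)) for d in DOFS}
    for i in range(n):
        st = chain_state(model, q[i])
        p_hip[i], p_knee[i], p_ankle[i] = st.p_hip, st.p_knee, st.p_ankle
        rots["thigh"][i], rots["shank"][i], rots["foot"][i] = (
            st.r_thigh, st.r_shank, st.r_foot)
        for s in segs:
            coms[s][i] = segment_com(model, st, s)
        for d in DOFS:
            axes[d][i] = st.axes[d]

    acc = {s: central_diff(central_diff(coms[s], dt), dt) for s in segs}
    omega = {s: _omega_from_rotations(rots[s], dt) for s in segs}
    alpha = {s: central_diff(omega[s], dt) for s in segs}

    def inertial_moment(seg: str) -> np.ndarray:
        inert = model.segments[seg].inertia
        r = rots[seg]
        i_w = np.einsum("nij,j,nkj->nik", r, inert, r)  # R I R^T
        l_dot = np.einsum("nij,nj->ni", i_w, alpha[seg])
        gyro = np.cross(omega[seg], np.einsum("nij,nj->ni", i_w, omega[seg]))
        return l_dot + gyro

    grf_force = np.asarray(grf_force, dtype=float)
    grf_cop = np.asarray(grf_cop, dtype=float)

    # foot: distal load is the GRF at the COP
    m_f = model.segments["foot"].mass
    f_ankle = m_f * (acc["foot"] - _G) - grf_force
    m_ankle = (inertial_moment("foot")
               - np.cross(p_ankle - coms["foot"], f_ankle)
               - np.cross(grf_cop - coms["foot"], grf_force))

    # shank: distal load is the negated foot proximal wrench at the ankle
    m_s = model.segments["shank"].mass
    f_knee = m_s * (acc["shank"] - _G) + f_ankle
    m_knee = (inertial_moment("shank")
              - np.cross(p_knee - coms["shank"], f_knee)
              - np.cross(p_ankle - coms["shank"], -f_ankle)
              + m_ankle)

    # thigh
    m_t = model.segments["thigh"].mass
    f_hip = m_t * (acc["thigh"] - _G) + f_knee
    m_hip = (inertial_moment("thigh")
             - np.cross(p_hip - coms["thigh"], f_hip)
             - np.cross(p_knee - coms["thigh"], -f_knee)
             + m_knee)

    moment_at = {"hip": m_hip, "knee": m_knee, "ankle": m_ankle, "subtalar": m_ankle}
    joint_for = {
        "hip_flexion": "hip", "hip_adduction": "hip", "hip_rotation": "hip",
        "knee_flexion": "knee", "knee_adduction": "knee", "knee_rotation": "knee",
        "ankle_dorsiflexion": "ankle", "subtalar_supination": "subtalar",
    }
    torques = {d: np.einsum("ni,ni->n", axes[d], moment_at[joint_for[d]]) for d in DOFS}

    shank_axis = np.einsum("nij,j->ni", rots["shank"], np.array([0.0, 1.0, 0.0]))
    time = np.arange(n) * dt
    return IDResult(time, torques, f_hip, f_knee, f_ankle, m_knee, axes,
                    shank_axis, p_knee)


def normalize_load(value, body_mass: float, barbell_mass: float):
    """Normalize a raw moment/force by total system mass (body + barbell), kg.

    Turns N m into N m/kg and N into N/kg, the units of the result tables.
    """
    if body_mass <= 0 or barbell_mass < 0:
        raise DynamicsError("body mass must be > 0 and barbell mass >= 0")
    return np.asarray(value, dtype=float) / (body_mass + barbell_mass)


#: extremum reported per table row, and how its sign is presented
MOMENT_ROW_SIGNS = {
    "hip_flexion_moment": ("min", "signed: extension-direction peak is negative"),
    "hip_adduction_moment": ("min", "signed: abduction-direction peak is negative"),
    "hip_internal_rotation_moment": ("min", "signed: external-direction peak is negative"),
    "knee_flexion_moment": ("min", "signed: extensor peak is negative"),
    "knee_internal_rotation_moment": ("min", "signed: external-direction peak is negative"),
    "knee_adduction_moment": ("ext_max",
                              "external frontal knee moment peak, medial-loading "
                              "(adduction) positive: max of the negated internal torque"),
    "ankle_extension_moment": ("absmin", "magnitude of the plantarflexion(-) peak"),
    "foot_valgus_moment": ("absmin", "magnitude of the valgus(-) peak"),
}

_ROW_DOF = {
    "hip_flexion_moment": "hip_flexion",
    "hip_adduction_moment": "hip_adduction",
    "hip_internal_rotation_moment": "hip_rotation",
    "knee_flexion_moment": "knee_flexion",
    "knee_internal_rotation_moment": "knee_rotation",
    "knee_adduction_moment": "knee_adduction",
    "ankle_extension_moment": "ankle_dorsiflexion",
    "foot_valgus_moment": "subtalar_supination",
}


def peak_moments(curves) -> dict[str, float]:
    """Peak joint moments with the result tables' row semantics.

    ``curves`` is a :class:`~squatmech.kinematics.CycleCurves` of normalized
    (N m/kg) moment curves keyed by DOF.  Rows whose convention-signed peak
    is negative (ankle plantarflexion, subtalar valgus) are reported as
    magnitudes; :data:`MOMENT_ROW_SIGNS` documents each row.
    """
    out = {}
    for row, (mode, _) in MOMENT_ROW_SIGNS.items():
        vals = curves[_ROW_DOF[row]]
        if mode == "max":
            out[row] = float(np.max(vals))
        elif mode == "min":
            out[row] = float(np.min(vals))
        elif mode == "ext_max":
            out[row] = float(np.max(-vals))
        else:  # absmin
            out[row] = float(abs(np.min(vals)))
    return out
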