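"""Static optimization of muscle activations and EMG envelope processing.

Per frame the muscle redistribution problem is the classic quadratic
program: minimize the sum of squared activations subject to the muscles
(moment arm x Fmax x activation) reproducing the net joint moments on every
constrained DOF, with activations bounded to [0, 1].  Reserve actuators --
high-cost idealized torques -- absorb whatever the bounded muscles cannot
deliver, mirroring common musculoskeletal-simulation practice, so the
moment balance holds identically at every frame.  Eliminating the reserve
torque turns each frame into a bound-constrained least-squares problem,
solved exactly by scipy's BVLS.

The knee frontal-plane (ab/adduction) DOF is excluded from the constraint
set by default: its moment is balanced by the medial/lateral contact-force
decomposition downstream, not by muscle recruitment.

EMG processing follows the study protocol: band-pass filtering (100-500 Hz
printed band; at a 1,000 Hz sampling rate the upper edge equals Nyquist, so
the realizable filter is the 100 Hz high-pass -- see the methods note),
moving-window RMS amplitude, and normalization by the maximum-voluntary-
contraction RMS onto a 0-1 activation scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear
from scipy.signal import butter, filtfilt
from scipy.stats import pearsonr

from .model import DOFS, BodyModel

#: DOFs whose net moment static optimization must reproduce (knee frontal
#: plane left to the tibiofemoral contact balance).
DEFAULT_SO_DOFS = tuple(d for d in DOFS if d != "knee_adduction")


class OptimizationError(RuntimeError):
    pass


class EmgError(ValueError):
    pass


@dataclass
class ActivationSolution:
    """Per-frame static-optimization result for one trial."""

    muscles: list[str]
    dofs: list[str]
    activations: dict[str, np.ndarray]     # muscle -> (n,), in [0, 1]
    forces: dict[str, np.ndarray]          # muscle -> (n,), N
    reserves: dict[str, np.ndarray]        # DOF -> (n,), N m of reserve torque
    objective: np.ndarray                  # (n,) sum of squared activations
    residual: dict[str, np.ndarray]        # DOF -> (n,) moment-balance residual

    def activation_matrix(self) -> np.ndarray:
        return np.column_stack([self.activations[m] for m in self.muscles])


def _solve_frame(a_mat: np.ndarray, tau: np.ndarray, weight: float) -> np.ndarray:
    """min ||a||^2 + weight * ||A a - tau||^2  s.t.  0 <= a <= 1.

    ``weight`` >= 1e10 encodes a hard equality (reserves disabled): the
    unconstrained stationary point is then the exact minimum-norm solution
    of A a = tau, which avoids the catastrophic conditioning of penalty
    normal equations.  Bound-active frames fall back to bounded least
    squares (BVLS) with the penalty capped where float64 QR stays accurate;
    feasibility is judged afterwards from the actual moment deficit.
    """
    nmus = a_mat.shape[1]
    if weight >= 1e10:
        a, *_ = np.linalg.lstsq(a_mat, tau, rcond=None)   # min-norm, exact
    else:
        sw = np.sqrt(weight)
        c = np.vstack([sw * a_mat, np.eye(nmus)])
        d = np.concatenate([sw * tau, np.zeros(nmus)])
        a, *_ = np.linalg.lstsq(c, d, rcond=None)
    if np.all((a >= 0.0) & (a <= 1.0)):
        return a
    sw = np.sqrt(min(weight, 1e8))
    c = np.vstack([sw * a_mat, np.eye(nmus)])
    d = np.concatenate([sw * tau, np.zeros(nmus)])
    res = lsq_linear(c, d, bounds=(0.0, 1.0), method="bvls")
    return res.x


def static_optimization(model: BodyModel, torques: dict[str, np.ndarray],
                        poses: dict[str, np.ndarray],
                        so_dofs: tuple[str, ...] = DEFAULT_SO_DOFS,
                        enable_reserves: bool = True,
                        reserve_weight: float = 1000.0,
                        residual_tol: float = 1e-6) -> ActivationSolution:
    """Distribute raw net joint moments (N m) among the model's muscles.

    ``poses`` holds the DOF angle series in degrees (moment arms may depend
    on them).  With reserves disabled, any frame whose moment balance cannot
    be met by bounded muscles alone raises, naming the offending DOFs.
    """
    dofs = list(so_dofs)
    muscles = list(model.muscles)
    n = len(next(iter(torques.values())))
    tau = np.column_stack([np.asarray(torques[d], dtype=float) for d in dofs])

    # (n, ndof, nmus) moment-generating matrix A = r_ij(pose) * Fmax_j
    arms = np.zeros((n, len(dofs), len(muscles)))
    for j, mname in enumerate(muscles):
        mus = model.muscles[mname]
        for i, dof in enumerate(dofs):
            coeffs = mus.arms.get(dof)
            if coeffs is None:
                continue
            theta = np.asarray(poses[dof], dtype=float)
            r = np.zeros(n)
            for k, ck in enumerate(coeffs):
                r += ck * theta**k
            arms[:, i, j] = r * mus.fmax

    weight = reserve_weight if enable_reserves else 1e12
    act = np.empty((n, len(muscles)))
    for f in range(n):
        act[f] = _solve_frame(arms[f], tau[f], weight)

    deficit = tau - np.einsum("nij,nj->ni", arms, act)
    if not enable_reserves:
        bad = np.abs(deficit) > residual_tol
        if np.any(bad):
            names = [dofs[i] for i in sorted(set(np.nonzero(bad)[1]))]
            raise OptimizationError(
                "static optimization infeasible without reserves on DOF(s): "
                + ", ".join(names))
        reserves = {d: np.zeros(n) for d in dofs}
        residual = {d: deficit[:, i] for i, d in enumerate(dofs)}
    else:
        # the reserve torque takes up the deficit: balance holds identically
        reserves = {d: deficit[:, i] for i, d in enumerate(dofs)}
        residual = {d: np.zeros(n) for d in dofs}

    fmax = np.array([model.muscles[m].fmax for m in muscles])
    forces = {m: act[:, j] * fmax[j] for j, m in enumerate(muscles)}
    return ActivationSolution(
        muscles=muscles,
        dofs=dofs,
        activations={m: act[:, j] for j, m in enumerate(muscles)},
        forces=forces,
        reserves=reserves,
        objective=np.sum(act**2, axis=1),
        residual=residual,
    )


# ---------------------------------------------------------------------------
# EMG processing
# ---------------------------------------------------------------------------


def emg_bandpass(raw: np.ndarray, rate: float,
                 band: tuple[float, float] = (100.0, 500.0),
                 order: int = 4, strict: bool = False) -> np.ndarray:
    """Zero-phase Butterworth band-pass of one EMG channel.

    If the upper band edge reaches Nyquist (as the printed 100-500 Hz band
    does at 1,000 Hz), the filter degenerates to the high-pass at the lower
    edge; ``strict=True`` raises instead.
    """
    nyq = rate / 2.0
    lo, hi = band
    if hi >= nyq:
        if strict:
            raise EmgError(f"band edge {hi:g} Hz is not below Nyquist ({nyq:g} Hz)")
        b, a = butter(order, lo / nyq, btype="highpass")
    else:
        b, a = butter(order, (lo / nyq, hi / nyq), btype="bandpass")
    return filtfilt(b, a, np.asarray(raw, dtype=float))


def emg_rms_envelope(filtered: np.ndarray, rate: float, window_ms: float = 100.0,
                     overlap: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Moving-window RMS amplitude; returns (window-centre times, RMS)."""
    if window_ms <= 0:
        raise EmgError("window length must be > 0")
    x = np.asarray(filtered, dtype=float)
    win = max(1, int(round(window_ms / 1000.0 * rate)))
    hop = max(1, int(round(win * (1.0 - overlap))))
    starts = np.arange(0, max(1, len(x) - win + 1), hop)
    rms = np.array([np.sqrt(np.mean(x[s:s + win] ** 2)) for s in starts])
    times = (starts + (win - 1) / 2.0) / rate
    return times, rms


@dataclass
class EmgEnvelope:
    """MVC-normalized activation estimate for one channel, clamped to [0, 1]."""

    times: np.ndarray
    values: np.ndarray
    window_ms: float
    mvc_rms: float


def normalize_mvc(times: np.ndarray, test_rms: np.ndarray, mvc_rms: float,
                  window_ms: float = 100.0) -> EmgEnvelope:
    """Normalize a test RMS series by the MVC reference RMS (0-1 scale)."""
    if mvc_rms <= 0:
        raise EmgError("MVC reference RMS must be > 0")
    vals = np.clip(np.asarray(test_rms, dtype=float) / mvc_rms, 0.0, 1.0)
    return EmgEnvelope(np.asarray(times, dtype=float), vals, window_ms, mvc_rms)


def validate_activations(emg_curves, so_curves, r_threshold: float = 0.7) -> pd.DataFrame:
    """Per-muscle similarity of EMG envelopes and static-optimization output.

    Both inputs are 101-sample cycle curve containers keyed by muscle.
    Returns a DataFrame with Pearson r, RMSE and a pass flag; a constant
    series makes r undefined and the muscle is reported (not NaN-propagated)
    with ``r = None`` and ``passed = False``.
    """
    rows = []
    for muscle in emg_curves.curves:
        e = emg_curves[muscle]
        s = so_curves[muscle]
        rmse = float(np.sqrt(np.mean((e - s) ** 2)))
        if np.std(e) < 1e-12 or np.std(s) < 1e-12:
            rows.append({"muscle": muscle, "r": None, "rmse": rmse,
                         "passed": False, "note": "constant series: r undefined"})
            continue
        r = float(pearsonr(e, s).statistic)
        rows.append({"muscle": muscle, "r": r, "rmse": rmse,
                     "passed": r >= r_threshold, "note": ""})
    return pd.DataFrame(rows).set_index("muscle")
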