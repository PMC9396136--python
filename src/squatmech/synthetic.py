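"""Synthetic squat cohort generator.

Emulates the study conditions end to end so every pipeline stage can be
exercised without any recorded data: two groups classified by standing
rearfoot valgus (>5 degrees, mild cases capped at 30), three barbell loads
(0, 30, 70% of the one-repetition maximum), three trials per condition,
and squat cycles that descend from upright to the deepest position and
return.

The kinematic template drives knee flexion with a C2-smooth sin^4 pulse
(zero velocity and acceleration at the quiet-standing boundaries); ankle
dorsiflexion and hip flexion share the pulse under the flat-foot constraint
(hip flexion = knee flexion - dorsiflexion keeps the foot flat on the
plate), and the pelvis is positioned each frame so the ankle stays pinned
above the force plate.  Markers are forward kinematics plus Gaussian noise;
the ground reaction force is the exact Newtonian resultant of the moving
segments plus the routed share of the supported (HAT + barbell) load, so
inverse dynamics can recover the generating joint torques; EMG channels
are band-limited carriers amplitude-modulated by the generating muscle
activations (themselves the static-optimization solution on the generating
torques), with an MVC reference bout for normalization.

Group effects default to the directions and rough magnitudes of the study's
result tables: deeper knee flexion (+10 degrees), more dorsiflexion, more
knee adduction, and a medially shifted centre of pressure that raises the
external knee adduction moment (about +0.12 N m/kg) and with it the medial
contact-force share.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as sio
from .dynamics import GRAVITY, inverse_dynamics
from .kinematics import angles_deg
from .model import (COORDS, DOFS, EMG_MUSCLES, BodyModel, LoadCondition,
                    Participant, build_default_model, chain_state,
                    marker_positions, neutral_q, rescale, segment_com)
from .neuromuscular import emg_bandpass, emg_rms_envelope, static_optimization
from .recording import GroundTruth, TrialRecording

_G_VEC = np.array([0.0, -GRAVITY, 0.0])


class GeneratorError(ValueError):
    pass


@dataclass(frozen=True)
class EffectSizes:
    """Valgus-minus-normal group offsets injected by the generator."""

    knee_flexion_deg: float = 10.0        # ~143.7 vs ~134.1 peak flexion
    dorsiflexion_deg: float = 4.0         # ~37.8 vs ~34.0 peak dorsiflexion
    knee_adduction_deg: float = 4.0       # deepest-position frontal knee angle
    knee_adduction_moment_nmkg: float = 0.12   # ~0.35 vs ~0.23 peak KAM

    @property
    def hip_flexion_deg(self) -> float:
        """Implied by the flat-foot constraint (hip = knee - dorsiflexion)."""
        return self.knee_flexion_deg - self.dorsiflexion_deg


@dataclass(frozen=True)
class NoiseLevels:
    marker_sd_m: float = 0.003
    grf_sd_n: float = 5.0
    cop_sd_m: float = 0.002
    emg_floor: float = 0.05     # additive carrier floor, fraction of MVC scale

    def __post_init__(self):
        if min(self.marker_sd_m, self.grf_sd_n, self.cop_sd_m, self.emg_floor) < 0:
            raise GeneratorError("noise SDs must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description for one synthetic cohort."""

    n_per_group: int = 10
    loads: tuple[float, ...] = LoadCondition.STUDY_FRACTIONS
    trials_per_condition: int = 3
    effects: EffectSizes = field(default_factory=EffectSizes)
    noise: NoiseLevels = field(default_factory=NoiseLevels)
    seed: int = 0
    marker_rate: float = 100.0
    emg_rate: float = 1000.0
    motion_duration_s: float = 3.4
    hold_s: float = 0.3
    mean_mass_kg: float = 65.67
    sd_mass_kg: float = 11.38
    mean_height_m: float = 1.72
    sd_height_m: float = 0.07
    one_rm_factor: float = 1.2
    base_kam_nmkg: float = 0.22           # normal-group external KAM scale

    def __post_init__(self):
        if self.n_per_group < 2 or self.trials_per_condition < 1:
            raise GeneratorError("need n >= 2 per group and >= 1 trial per condition")


def _subseed(seed: int, *parts) -> np.random.Generator:
    """Deterministic child generator from a base seed and string parts."""
    h = hashlib.sha256(("|".join(str(p) for p in parts)).encode()).digest()
    return np.random.default_rng([seed & 0x7FFFFFFF, int.from_bytes(h[:4], "big")])


def truth_model(participant: Participant) -> BodyModel:
    """The participant's generating model (scaled by definition)."""
    return rescale(build_default_model(participant), {})


# ---------------------------------------------------------------------------
# participants
# ---------------------------------------------------------------------------


def generate_participant(group: str, seed: int, spec: CohortSpec | None = None,
                         index: int = 0) -> Participant:
    """Draw one participant of the given group ("valgus" or "normal")."""
    if group not in ("valgus", "normal"):
        raise GeneratorError(f"unknown group label {group!r}")
    spec = spec or CohortSpec()
    rng = _subseed(seed, "participant", group, index)
    mass = float(np.clip(rng.normal(spec.mean_mass_kg, spec.sd_mass_kg), 45.0, 110.0))
    height = float(np.clip(rng.normal(spec.mean_height_m, spec.sd_height_m), 1.50, 1.95))
    if group == "valgus":
        angle = float(rng.uniform(6.0, 30.0))
    else:
        angle = float(rng.uniform(0.0, 4.99))
    one_rm = float(spec.one_rm_factor * mass * np.clip(rng.normal(1.0, 0.1), 0.7, 1.3))
    return Participant(id=f"{group[0].upper()}{index:02d}", mass=mass, height=height,
                       valgus_angle=angle, one_rm=one_rm, group=group)


# ---------------------------------------------------------------------------
# kinematic template
# ---------------------------------------------------------------------------


def _pulse(time: np.ndarray, t0: float, duration: float) -> np.ndarray:
    """C2-smooth unit pulse: sin^4(pi u) over the motion window, 0 outside."""
    u = (time - t0) / duration
    s = np.zeros_like(time)
    inside = (u >= 0.0) & (u <= 1.0)
    s[inside] = np.sin(np.pi * u[inside]) ** 4
    return s


@dataclass
class _Template:
    time: np.ndarray
    q: np.ndarray            # (n, 11), angles rad
    deepest_index: int
    pulse: np.ndarray        # the 0->1->0 depth profile s(t)
    cop_x: np.ndarray        # absolute anterior COP position per frame, m
    knee_z: np.ndarray       # mediolateral knee-centre track, m
    kam_target_nm: float     # raw external knee adduction moment amplitude


def _build_template(participant: Participant, load: LoadCondition,
                    model: BodyModel, spec: CohortSpec,
                    rng: np.random.Generator) -> _Template:
    """Joint-angle template for one trial.

    Subject-level traits (habitual depth, tempo, frontal posture, adduction-
    moment scale) are drawn from a generator seeded by the cohort seed and
    participant id, so a participant's repeated trials are correlated;
    trial-to-trial jitter comes from the per-trial generator ``rng``.
    """
    eff = spec.effects
    valgus = participant.group == "valgus"
    traits = _subseed(spec.seed, "traits", participant.id)

    tempo_s = float(np.clip(traits.normal(spec.motion_duration_s, 0.25), 2.5, 4.5))
    kf_s = traits.normal(134.0, 5.0) + (eff.knee_flexion_deg if valgus else 0.0)
    df_s = traits.normal(34.0, 2.5) + (eff.dorsiflexion_deg if valgus else 0.0)
    # frontal/transverse excursions stay small: squatters keep the knee near
    # the ground-reaction line; the valgus group squats with slightly less
    # hip abduction and more frontal knee excursion
    ka_s = traits.normal(2.0, 1.0) + (eff.knee_adduction_deg if valgus else 0.0)
    abd_s = max(traits.normal(8.0, 2.0) - (2.0 if valgus else 0.0), 2.0)
    hip_rot_s = traits.normal(10.0, 3.0)
    knee_rot_s = traits.normal(10.0, 3.0)
    sup_amp_s = float(np.clip(traits.normal(16.0, 4.0), 5.0, 28.0))
    kam_mult_s = float(np.clip(traits.normal(1.0, 0.2), 0.3, 1.7))

    tempo = float(np.clip(tempo_s + rng.normal(0.0, 0.10), 2.4, 4.6))
    n = int(round((tempo + 2 * spec.hold_s) * spec.marker_rate)) + 1
    time = np.arange(n) / spec.marker_rate
    s = _pulse(time, spec.hold_s, tempo)

    kf_max = float(np.clip(kf_s + rng.normal(0.0, 1.0), 100.0, 155.0))
    df_max = float(np.clip(df_s + rng.normal(0.0, 0.5), 20.0, 0.4 * kf_max))
    hf_max = kf_max - df_max                       # flat-foot constraint
    ka_max = ka_s + rng.normal(0.0, 0.5)
    sup_base = 0.3 * participant.valgus_angle

    deg = {
        "hip_flexion": hf_max * s,
        "hip_adduction": -abd_s * s,
        "hip_rotation": hip_rot_s * s,
        "knee_flexion": kf_max * s,
        "knee_adduction": ka_max * s,
        "knee_rotation": knee_rot_s * s,
        "ankle_dorsiflexion": df_max * s,
        "subtalar_supination": -(sup_base + sup_amp_s * s),
    }

    # pin the ankle above the plate by solving the pelvis translation
    q = np.zeros((n, len(COORDS)))
    for i, d in enumerate(DOFS):
        q[:, 3 + i] = np.radians(deg[d])
    q0 = neutral_q(model)
    st0 = chain_state(model, q0)
    ankle_target = st0.p_ankle
    lt = model.segments["thigh"].length
    lf = model.segments["foot"].length
    ls = model.segments["shank"].length
    knee_z = np.empty(n)
    for i in range(n):
        st = chain_state(model, q[i])
        down_t = st.r_thigh @ np.array([0.0, -lt, 0.0])
        down_s = st.r_shank @ np.array([0.0, -ls, 0.0])
        q[i, 0:3] = ankle_target - model.hip_offset - down_t - down_s
        knee_z[i] = ankle_target[2] + (-down_s)[2]   # knee relative to plate

    # COP drifts toward the heel at depth (dorsiflexion demand at the bottom)
    cop_x = ankle_target[0] + (0.30 - 0.35 * s) * lf

    m_sys = participant.mass + load.barbell_mass
    # subject-to-subject spread on the habitual baseline; the group effect
    # is the additive offset the effect record specifies
    kam = (spec.base_kam_nmkg * kam_mult_s
           + (eff.knee_adduction_moment_nmkg if valgus else 0.0)
           + rng.normal(0.0, 0.02))
    return _Template(time, q, int(np.argmax(s)), s, cop_x, knee_z,
                     kam_target_nm=kam * m_sys)


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------


def _exact_grf(model: BodyModel, template: _Template, barbell_mass: float,
               rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Newtonian ground reaction of the generating motion (noise-free).

    The force is the resultant of the moving leg segments plus the routed
    share of the supported (HAT + barbell) point load at the hip.  The
    mediolateral COP position is then solved per frame so that the external
    knee ab/adduction moment follows the template's target pulse exactly:
    a first inverse-dynamics pass with the COP on the knee line gives the
    geometric baseline torque, and the linear sensitivity of the knee
    frontal torque to a mediolateral COP offset closes the loop.
    """
    n = len(template.time)
    dt = 1.0 / rate
    coms = {s: np.empty((n, 3)) for s in ("thigh", "shank", "foot")}
    p_hip = np.empty((n, 3))
    for i in range(n):
        st = chain_state(model, template.q[i])
        p_hip[i] = st.p_hip
        for s in coms:
            coms[s][i] = segment_com(model, st, s)
    acc = {s: np.gradient(np.gradient(coms[s], dt, axis=0), dt, axis=0) for s in coms}
    a_hip = np.gradient(np.gradient(p_hip, dt, axis=0), dt, axis=0)

    m_up = model.segments["pelvis"].mass + barbell_mass
    share = model.weight_share
    force = np.zeros((n, 3))
    for s in coms:
        force += model.segments[s].mass * (acc[s] - _G_VEC)
    force += share * m_up * (a_hip - _G_VEC)

    cop = np.zeros((n, 3))
    cop[:, 0] = template.cop_x
    cop[:, 2] = template.knee_z
    idr0 = inverse_dynamics(model, template.q, rate, force, cop)

    # target internal frontal torque: -(external adduction target)
    tau_target = -template.kam_target_nm * template.pulse
    axes = idr0.axes["knee_adduction"]
    # moment change per metre of medial (-z) COP shift
    gain = axes[:, 0] * force[:, 1] - axes[:, 1] * force[:, 0]
    gain = np.where(np.abs(gain) < 50.0, np.sign(gain) * 50.0 + (gain == 0) * 50.0,
                    gain)
    delta = (tau_target - idr0.torques["knee_adduction"]) / -gain
    delta = np.clip(delta, -0.20, 0.20)
    cop[:, 2] = template.knee_z - delta
    return force, cop


def generate_squat_trial(participant: Participant, load: LoadCondition,
                         model: BodyModel, spec: CohortSpec,
                         seed: int) -> TrialRecording:
    """Synthesize one squat trial with attached ground truth."""
    if not model.scaled:
        raise GeneratorError("model must be scaled to the participant")
    rng = _subseed(seed, "trial", participant.id, load.fraction)
    template = _build_template(participant, load, model, spec, rng)
    n = len(template.time)

    # markers: forward kinematics + noise
    clean = {m: np.empty((n, 3)) for m in model.marker_names()}
    for i in range(n):
        pos = marker_positions(model, template.q[i])
        for m, p in pos.items():
            clean[m][i] = p
    markers = {m: v + rng.normal(0.0, spec.noise.marker_sd_m, v.shape)
               for m, v in clean.items()}

    force, cop = _exact_grf(model, template, load.barbell_mass, spec.marker_rate)
    noisy_force = force + rng.normal(0.0, spec.noise.grf_sd_n, force.shape)
    noisy_force[:, 1] = np.clip(noisy_force[:, 1], 0.0, None)
    noisy_cop = cop + rng.normal(0.0, spec.noise.cop_sd_m, cop.shape)

    # generating torques and activations
    idr = inverse_dynamics(model, template.q, spec.marker_rate, force, cop)
    poses = angles_deg(template.q)
    sol = static_optimization(model, idr.torques, poses)
    activations = {m: sol.activations[m] for m in EMG_MUSCLES}

    emg, mvc_rms = _synthesize_emg(activations, spec, rng)

    truth = GroundTruth(q=template.q, torques=idr.torques, activations=activations,
                        grf_force=force, grf_cop=cop,
                        deepest_index=template.deepest_index)
    return TrialRecording(
        participant_id=participant.id, load_fraction=load.fraction,
        markers=markers, marker_rate=spec.marker_rate,
        grf_force=noisy_force, grf_cop=noisy_cop,
        emg=emg, emg_rate=spec.emg_rate, mvc_rms=mvc_rms, ground_truth=truth)


def _carrier(rng: np.random.Generator, n: int, rate: float) -> np.ndarray:
    """Unit-RMS band-limited (100-450 Hz) EMG carrier noise."""
    x = rng.normal(0.0, 1.0, n)
    nyq = rate / 2.0
    from scipy.signal import butter, filtfilt
    b, a = butter(4, (100.0 / nyq, 450.0 / nyq), btype="bandpass")
    y = filtfilt(b, a, x)
    return y / np.std(y)


def _synthesize_emg(activations: dict[str, np.ndarray], spec: CohortSpec,
                    rng: np.random.Generator):
    """Amplitude-modulated carriers + MVC reference RMS per channel."""
    gain = 1e-3     # volts at full activation
    n100 = len(next(iter(activations.values())))
    t100 = np.arange(n100) / spec.marker_rate
    n1000 = int(round(n100 * spec.emg_rate / spec.marker_rate))
    t1000 = np.arange(n1000) / spec.emg_rate
    emg = {}
    mvc_rms = {}
    for muscle, act in activations.items():
        act_hi = np.interp(t1000, t100, act)
        signal = gain * act_hi * _carrier(rng, n1000, spec.emg_rate)
        signal += gain * spec.noise.emg_floor * _carrier(rng, n1000, spec.emg_rate)
        emg[muscle] = signal
        # MVC bout: modulation = 1 for 2 s, processed like a test bout
        mvc = gain * _carrier(rng, int(2 * spec.emg_rate), spec.emg_rate)
        filt = emg_bandpass(mvc, spec.emg_rate)
        _, rms = emg_rms_envelope(filt, spec.emg_rate)
        mvc_rms[muscle] = float(np.mean(rms))
    return emg, mvc_rms


def generate_static_trial(participant: Participant, model: BodyModel,
                          spec: CohortSpec, seed: int) -> TrialRecording:
    """Quiet upright standing for model scaling (1 s)."""
    if not model.scaled:
        raise GeneratorError("model must be scaled to the participant")
    rng = _subseed(seed, "static", participant.id)
    n = int(spec.marker_rate)
    q = np.tile(neutral_q(model), (n, 1))
    clean = {m: np.empty((n, 3)) for m in model.marker_names()}
    pos = marker_positions(model, q[0])
    for m, p in pos.items():
        clean[m][:] = p
    markers = {m: v + rng.normal(0.0, spec.noise.marker_sd_m, v.shape)
               for m, v in clean.items()}
    routed = (model.weight_share * model.segments["pelvis"].mass
              + sum(model.segments[s].mass for s in ("thigh", "shank", "foot")))
    force = np.zeros((n, 3))
    force[:, 1] = routed * GRAVITY
    cop = np.zeros((n, 3))
    return TrialRecording(participant_id=participant.id, load_fraction=0.0,
                          markers=markers, marker_rate=spec.marker_rate,
                          grf_force=force, grf_cop=cop)


# ---------------------------------------------------------------------------
# cohort on disk
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec, out_dir) -> dict:
    """Write a full cohort (TRC + CSV per trial, manifest) and return the manifest."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    manifest: dict = {
        "seed": spec.seed,
        "n_per_group": spec.n_per_group,
        "loads": list(spec.loads),
        "trials_per_condition": spec.trials_per_condition,
        "effects": asdict(spec.effects),
        "noise": asdict(spec.noise),
        "participants": [],
        "trials": [],
    }
    for group in ("valgus", "normal"):
        for idx in range(spec.n_per_group):
            part = generate_participant(group, spec.seed, spec, index=idx)
            model = truth_model(part)
            static = generate_static_trial(part, model, spec, spec.seed)
            static_file = f"{part.id}_static.trc"
            sio.write_trc(out / static_file, static.markers, spec.marker_rate)
            pinfo = {
                "id": part.id, "group": group, "mass_kg": round(part.mass, 6),
                "height_m": round(part.height, 6),
                "valgus_angle_deg": round(part.valgus_angle, 6),
                "one_rm_kg": round(part.one_rm, 6),
                "static_trc": static_file, "mvc_rms": None,
            }
            for load_f in spec.loads:
                load = LoadCondition(load_f, part.one_rm)
                for k in range(spec.trials_per_condition):
                    tseed = (spec.seed * 1_000_003 + idx * 101 + k) & 0x7FFFFFFF
                    trial = generate_squat_trial(
                        part, load, model, spec,
                        seed=tseed + int(load_f * 100))
                    stem = f"{part.id}_L{int(round(load_f * 100)):02d}_T{k + 1}"
                    sio.write_trc(out / f"{stem}.trc", trial.markers, spec.marker_rate)
                    sio.write_grf(out / f"{stem}_grf.csv", trial.time,
                                  trial.grf_force, trial.grf_cop)
                    sio.write_emg(out / f"{stem}_emg.csv", trial.emg_time, trial.emg)
                    if pinfo["mvc_rms"] is None:
                        pinfo["mvc_rms"] = {k_: round(v, 10)
                                            for k_, v in trial.mvc_rms.items()}
                    manifest["trials"].append({
                        "participant": part.id, "group": group,
                        "load_fraction": load_f, "trial": k + 1,
                        "trc": f"{stem}.trc", "grf": f"{stem}_grf.csv",
                        "emg": f"{stem}_emg.csv",
                        "barbell_mass_kg": round(load.barbell_mass, 6),
                    })
            manifest["participants"].append(pinfo)
    sio.write_manifest(out / "manifest.json", manifest)
    return manifest
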