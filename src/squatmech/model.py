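"""Reduced lower-limb rigid-body model for barbell-squat analysis.

The model is a single (right-leg) kinematic chain: a pelvis+HAT root segment
carrying the trunk, head, arms and contralateral leg as a point load, then
thigh, shank and foot segments connected by a 3-DOF hip, a 3-DOF knee
(flexion, ab/adduction and axial rotation are all free), a 1-DOF ankle and a
1-DOF subtalar joint.  Segment inertial parameters follow published
anthropometric regression fractions of body mass and stature; muscles are
rigid-tendon, activation-proportional force elements with explicit signed
moment-arm functions (constant or low-order polynomial in the joint angle).

Sign conventions, fixed across the whole pipeline:
flexion (+) / extension (-); abduction (-) / adduction (+);
dorsiflexion (+) / plantarflexion (-); supination (+) / valgus (-);
internal rotation (+) / external rotation (-).

Lab frame: X anterior, Y up, Z to the subject's right (lateral for the
right leg).  All lengths in metres, masses in kg, angles in degrees at
module interfaces and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

GRAVITY = 9.81

#: Generalized coordinates of the chain: pelvis translation + 8 joint DOFs.
TRANSLATIONS = ("pelvis_tx", "pelvis_ty", "pelvis_tz")
DOFS = (
    "hip_flexion",
    "hip_adduction",
    "hip_rotation",
    "knee_flexion",
    "knee_adduction",
    "knee_rotation",
    "ankle_dorsiflexion",
    "subtalar_supination",
)
COORDS = TRANSLATIONS + DOFS

#: Human-readable positive direction per DOF (the fixed sign convention).
SIGN_CONVENTION = {
    "hip_flexion": "flexion(+)/extension(-)",
    "hip_adduction": "adduction(+)/abduction(-)",
    "hip_rotation": "internal(+)/external(-)",
    "knee_flexion": "flexion(+)/extension(-)",
    "knee_adduction": "adduction(+)/abduction(-)",
    "knee_rotation": "internal(+)/external(-)",
    "ankle_dorsiflexion": "dorsiflexion(+)/plantarflexion(-)",
    "subtalar_supination": "supination(+)/valgus(-)",
}

#: The four surface-EMG-monitored muscles used for model validation.
EMG_MUSCLES = ("rectus_femoris", "biceps_femoris", "tibialis_anterior", "gastrocnemius")


class ModelError(ValueError):
    """Invalid participant or model definition."""


class LookupError_(KeyError):
    """Unknown muscle or DOF name."""


def encode_sign(dof: str, anatomical_value: float, direction: str) -> float:
    """Map an unsigned anatomical magnitude onto the signed convention.

    ``direction`` is one of the two labels in :data:`SIGN_CONVENTION` for the
    DOF (e.g. ``"extension"`` for a knee DOF).
    """
    pos, neg = _parse_convention(dof)
    if direction == pos:
        return float(anatomical_value)
    if direction == neg:
        return -float(anatomical_value)
    raise LookupError_(f"direction {direction!r} not valid for DOF {dof!r}")


def decode_sign(dof: str, signed_value: float) -> tuple[float, str]:
    """Inverse of :func:`encode_sign`: signed value -> (magnitude, direction)."""
    pos, neg = _parse_convention(dof)
    if signed_value >= 0:
        return float(signed_value), pos
    return float(-signed_value), neg


def _parse_convention(dof: str) -> tuple[str, str]:
    try:
        conv = SIGN_CONVENTION[dof]
    except KeyError as exc:
        raise LookupError_(f"unknown DOF {dof!r}") from exc
    pos, neg = conv.split("/")
    return pos.rstrip("(+)"), neg.rstrip("(-)")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Participant:
    """Anthropometrics and grouping data for one subject."""

    id: str
    mass: float          # kg
    height: float        # m
    valgus_angle: float  # static standing rearfoot valgus, degrees, >= 0
    one_rm: float        # back-squat one-repetition maximum, kg
    group: str           # "valgus" | "normal"

    def __post_init__(self):
        if not (self.mass > 0 and self.height > 0 and self.one_rm > 0):
            raise ModelError("mass, height and 1RM must be positive")
        if not (0.0 <= self.valgus_angle <= 30.0):
            raise ModelError("static rearfoot valgus angle must lie in [0, 30] degrees")
        expected = "valgus" if self.valgus_angle > 5.0 else "normal"
        if self.group != expected:
            raise ModelError(
                f"group label {self.group!r} inconsistent with the 5-degree rule "
                f"for angle {self.valgus_angle:.2f}"
            )


@dataclass(frozen=True)
class LoadCondition:
    """External barbell load as a fraction of the one-repetition maximum."""

    fraction: float
    one_rm: float

    STUDY_FRACTIONS = (0.0, 0.3, 0.7)

    def __post_init__(self):
        if self.fraction < 0 or self.one_rm <= 0:
            raise ModelError("load fraction must be >= 0 and 1RM > 0")

    @property
    def barbell_mass(self) -> float:
        return self.fraction * self.one_rm

    @classmethod
    def study_conditions(cls, one_rm: float) -> list["LoadCondition"]:
        return [cls(f, one_rm) for f in cls.STUDY_FRACTIONS]


@dataclass
class Segment:
    name: str
    mass: float            # kg
    length: float          # m (pelvis: hip-offset scale length)
    com_offset: float      # fraction of length from the proximal end
    inertia: np.ndarray    # (3,) principal moments in the segment frame, kg m^2

    def __post_init__(self):
        self.inertia = np.asarray(self.inertia, dtype=float)
        if self.mass <= 0 or self.length <= 0 or np.any(self.inertia <= 0):
            raise ModelError(f"segment {self.name}: mass/length/inertia must be > 0")


@dataclass
class MuscleElement:
    """Rigid-tendon actuator: force = activation * Fmax along its line of action.

    ``arms`` maps DOF name -> polynomial coefficients ``(c0, c1, ...)`` giving
    the signed moment arm in metres as a function of that DOF's angle in
    degrees: ``r(theta) = c0 + c1*theta + c2*theta**2 ...``.  A positive arm
    produces a moment in the positive convention direction of the DOF.
    ``knee_axial_factor`` is the fraction of the muscle force transmitted as
    compression along the tibial long axis (non-zero only for knee spanners).
    """

    name: str
    fmax: float
    arms: dict[str, tuple[float, ...]] = field(default_factory=dict)
    knee_axial_factor: float = 0.0

    def __post_init__(self):
        if self.fmax <= 0:
            raise ModelError(f"muscle {self.name}: Fmax must be > 0")
        for dof in self.arms:
            if dof not in DOFS:
                raise LookupError_(f"muscle {self.name}: unknown DOF {dof!r}")

    def moment_arm(self, dof: str, pose: dict[str, float]) -> float:
        """Signed moment arm (m) at the given pose (DOF angles in degrees)."""
        if dof not in DOFS:
            raise LookupError_(f"unknown DOF {dof!r}")
        coeffs = self.arms.get(dof)
        if coeffs is None:
            return 0.0
        theta = float(pose.get(dof, 0.0))
        return float(sum(c * theta**k for k, c in enumerate(coeffs)))

    @property
    def spans_knee(self) -> bool:
        return any(d.startswith("knee") for d in self.arms)


@dataclass
class BodyModel:
    """Scaled rigid-segment linkage with markers and muscle elements."""

    segments: dict[str, Segment]
    muscles: dict[str, MuscleElement]
    markers: dict[str, tuple[str, np.ndarray]]   # name -> (segment, local offset m)
    hip_offset: np.ndarray                       # hip centre in the pelvis frame
    foot_com_drop: float                         # vertical drop of foot COM below ankle
    tibial_plateau_width: float                  # m
    weight_share: float = 0.5                    # fraction of upper load on this leg
    scaled: bool = False
    scale_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.hip_offset = np.asarray(self.hip_offset, dtype=float)
        self.markers = {
            k: (seg, np.asarray(off, dtype=float)) for k, (seg, off) in self.markers.items()
        }
        if self.tibial_plateau_width <= 0:
            raise ModelError("tibial plateau width must be > 0")
        for name in ("pelvis", "thigh", "shank", "foot"):
            if name not in self.segments:
                raise ModelError(f"missing segment {name!r}")
        for m in EMG_MUSCLES:
            if m not in self.muscles:
                raise ModelError(f"missing EMG-monitored muscle {m!r}")
        for name, (seg, _) in self.markers.items():
            if seg not in self.segments:
                raise ModelError(f"marker {name!r} maps to unknown segment {seg!r}")

    # -- convenience -------------------------------------------------------
    @property
    def total_mass(self) -> float:
        return sum(s.mass for s in self.segments.values())

    def marker_names(self) -> list[str]:
        return list(self.markers)

    def moment_arm(self, muscle: str, dof: str, pose: dict[str, float]) -> float:
        try:
            mus = self.muscles[muscle]
        except KeyError as exc:
            raise LookupError_(f"unknown muscle {muscle!r}") from exc
        return mus.moment_arm(dof, pose)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "segments": {
                n: {
                    "mass": s.mass,
                    "length": s.length,
                    "com_offset": s.com_offset,
                    "inertia": [float(v) for v in s.inertia],
                }
                for n, s in self.segments.items()
            },
            "muscles": {
                n: {
                    "fmax": m.fmax,
                    "arms": {d: list(c) for d, c in m.arms.items()},
                    "knee_axial_factor": m.knee_axial_factor,
                }
                for n, m in self.muscles.items()
            },
            "markers": {n: [seg, [float(v) for v in off]] for n, (seg, off) in self.markers.items()},
            "hip_offset": [float(v) for v in self.hip_offset],
            "foot_com_drop": self.foot_com_drop,
            "tibial_plateau_width": self.tibial_plateau_width,
            "weight_share": self.weight_share,
            "scaled": self.scaled,
            "scale_factors": dict(self.scale_factors),
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "BodyModel":
        return cls(
            segments={
                n: Segment(n, s["mass"], s["length"], s["com_offset"], np.asarray(s["inertia"]))
                for n, s in d["segments"].items()
            },
            muscles={
                n: MuscleElement(
                    n,
                    m["fmax"],
                    {dof: tuple(c) for dof, c in m["arms"].items()},
                    m.get("knee_axial_factor", 0.0),
                )
                for n, m in d["muscles"].items()
            },
            markers={n: (seg, np.asarray(off)) for n, (seg, off) in d["markers"].items()},
            hip_offset=np.asarray(d["hip_offset"]),
            foot_com_drop=d["foot_com_drop"],
            tibial_plateau_width=d["tibial_plateau_width"],
            weight_share=d.get("weight_share", 0.5),
            scaled=d.get("scaled", False),
            scale_factors=d.get("scale_factors", {}),
        )

    @classmethod
    def from_yaml(cls, path) -> "BodyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# default model construction
# ---------------------------------------------------------------------------

# Anthropometric fractions (mass fraction of body mass; length fraction of
# stature; COM fraction from the proximal end; radii of gyration as fractions
# of segment length about transverse / longitudinal axes).
_SEG_PARAMS = {
    "thigh": dict(mass=0.1416, length=0.245, com=0.41, k_t=0.329, k_l=0.149),
    "shank": dict(mass=0.0433, length=0.246, com=0.44, k_t=0.255, k_l=0.103),
    "foot": dict(mass=0.0137, length=0.152, com=0.44, k_t=0.257, k_l=0.124),
}


def _default_muscles() -> dict[str, MuscleElement]:
    """Right-leg actuator set.

    Arms are representative adult values; knee extensors carry negative arms
    on the flexion DOF (extension is negative under the convention).  The
    vasti arm shortens slightly with knee flexion, a well-known feature of
    the extensor mechanism.
    """
    defs = [
        # the extensor mechanism pulls laterally (Q-angle), giving the
        # quadriceps a frontal-plane abduction moment about the knee; the
        # -0.025 m neutral offset puts the baseline medial compartment share
        # near the ~25% the contact-force literature reports, and knee
        # adduction (varus alignment) rotates the pull medially, shrinking
        # the lateral cancellation by ~1.2 mm per degree
        # the RF hip-flexion arm shortens as the hip flexes, so deep in the
        # squat it acts mainly as a knee extensor
        ("rectus_femoris", 2000,
         {"hip_flexion": (0.040, -3.0e-4), "knee_flexion": (-0.044, 4e-5),
          "knee_adduction": (-0.025, 1.2e-3)}, 1.0),
        ("vasti", 6000,
         {"knee_flexion": (-0.048, 4e-5), "knee_adduction": (-0.025, 1.2e-3)}, 1.0),
        ("biceps_femoris", 1800,
         {"hip_flexion": (-0.055,), "knee_flexion": (0.030,),
          "knee_adduction": (-0.012,)}, 0.9),
        ("medial_hamstrings", 1800,
         {"hip_flexion": (-0.055,), "knee_flexion": (0.032,),
          "knee_adduction": (0.012,)}, 0.9),
        ("gluteus_maximus", 3200, {"hip_flexion": (-0.062,), "hip_rotation": (-0.020,)}, 0.0),
        ("iliopsoas", 1600, {"hip_flexion": (0.042,)}, 0.0),
        ("gluteus_medius", 2800, {"hip_adduction": (-0.055,)}, 0.0),
        ("adductor_group", 2400, {"hip_adduction": (0.045,)}, 0.0),
        ("hip_internal_rotators", 600, {"hip_rotation": (0.025,)}, 0.0),
        ("hip_external_rotators", 600, {"hip_rotation": (-0.025,)}, 0.0),
        ("gastrocnemius", 2800, {"knee_flexion": (0.020,), "ankle_dorsiflexion": (-0.042,)}, 0.9),
        ("soleus", 4000, {"ankle_dorsiflexion": (-0.040,), "subtalar_supination": (0.008,)}, 0.0),
        ("tibialis_anterior", 1200,
         {"ankle_dorsiflexion": (0.035,), "subtalar_supination": (0.012,)}, 0.0),
        ("peroneals", 1000, {"ankle_dorsiflexion": (-0.010,), "subtalar_supination": (-0.015,)}, 0.0),
        ("tibialis_posterior", 1500,
         {"ankle_dorsiflexion": (-0.012,), "subtalar_supination": (0.014,)}, 0.0),
    ]
    return {n: MuscleElement(n, f, arms, ax) for n, f, arms, ax in defs}


def _default_markers(height: float, lt: float, ls: float, lf: float) -> dict:
    s = height / 1.72  # global anthropometric scale for transverse offsets
    return {
        # pelvis (frame origin at mid-pelvis)
        "RASI": ("pelvis", (0.08 * s, 0.02 * s, 0.12 * s)),
        "LASI": ("pelvis", (0.08 * s, 0.02 * s, -0.12 * s)),
        "RPSI": ("pelvis", (-0.09 * s, 0.03 * s, 0.04 * s)),
        "LPSI": ("pelvis", (-0.09 * s, 0.03 * s, -0.04 * s)),
        # thigh (origin at hip, long axis -Y)
        "THI1": ("thigh", (0.05 * s, -0.30 * lt, 0.03 * s)),
        "THI2": ("thigh", (-0.02 * s, -0.45 * lt, 0.05 * s)),
        "THI3": ("thigh", (0.04 * s, -0.70 * lt, 0.045 * s)),
        "KNEL": ("thigh", (0.0, -lt, 0.05 * s)),
        "KNEM": ("thigh", (0.0, -lt, -0.05 * s)),
        # shank (origin at knee)
        "TIB1": ("shank", (0.04 * s, -0.25 * ls, 0.03 * s)),
        "TIB2": ("shank", (-0.01 * s, -0.50 * ls, 0.05 * s)),
        "ANKL": ("shank", (0.0, -ls, 0.04 * s)),
        "ANKM": ("shank", (0.0, -ls, -0.04 * s)),
        # foot (origin at ankle, long axis +X)
        "HEEL": ("foot", (-0.04 * s, -0.03 * s, 0.0)),
        "TOE": ("foot", (lf - 0.02 * s, -0.05 * s, 0.0)),
        "MT1": ("foot", (0.60 * lf, -0.05 * s, -0.035 * s)),
        "MT5": ("foot", (0.55 * lf, -0.05 * s, 0.045 * s)),
    }


def build_default_model(participant: Participant, weight_share: float = 0.5) -> BodyModel:
    """Build an unscaled model from participant anthropometrics.

    Segment masses and lengths follow the anthropometric fractions in
    ``_SEG_PARAMS``; the pelvis+HAT segment absorbs the remaining body mass
    (trunk, head, arms and the contralateral leg), so the segment masses sum
    to the participant mass exactly.
    """
    m, h = participant.mass, participant.height
    segments: dict[str, Segment] = {}
    leg_mass = 0.0
    for name, p in _SEG_PARAMS.items():
        sm = p["mass"] * m
        sl = p["length"] * h
        it = sm * (p["k_t"] * sl) ** 2
        il = sm * (p["k_l"] * sl) ** 2
        # long axis is Y for thigh/shank, X for the foot
        inertia = (il, it, it) if name == "foot" else (it, il, it)
        segments[name] = Segment(name, sm, sl, p["com"], np.array(inertia))
        leg_mass += sm
    pelvis_len = 0.10 * h
    pelvis_mass = m - leg_mass
    kp = 0.35 * pelvis_len
    segments["pelvis"] = Segment(
        "pelvis", pelvis_mass, pelvis_len, 0.5,
        np.array([pelvis_mass * kp**2] * 3),
    )

    lt, ls, lf = segments["thigh"].length, segments["shank"].length, segments["foot"].length
    s = h / 1.72
    return BodyModel(
        segments=segments,
        muscles=_default_muscles(),
        markers=_default_markers(h, lt, ls, lf),
        hip_offset=np.array([0.0, -0.03 * s, 0.09 * s]),
        foot_com_drop=0.04 * s,
        tibial_plateau_width=0.08 * s,
        weight_share=weight_share,
    )


# ---------------------------------------------------------------------------
# kinematic chain
# ---------------------------------------------------------------------------


def _rx(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _ry(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rz(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class ChainState:
    """Joint centres, segment rotations and DOF axes at one pose."""

    p_pelvis: np.ndarray
    p_hip: np.ndarray
    p_knee: np.ndarray
    p_ankle: np.ndarray
    r_pelvis: np.ndarray
    r_thigh: np.ndarray
    r_shank: np.ndarray
    r_foot: np.ndarray
    axes: dict[str, np.ndarray]      # rotational DOF -> world-frame axis
    joint_of: dict[str, np.ndarray]  # rotational DOF -> world joint centre


def chain_state(model: BodyModel, q: np.ndarray) -> ChainState:
    """Forward kinematics of the chain at generalized coordinates ``q``.

    ``q`` is length 11: pelvis translation (m) then the 8 DOF angles in
    radians, ordered as :data:`COORDS`.
    """
    tx, ty, tz, hf, ha, hr, kf, ka, kr, df, sup = q
    p_pelvis = np.array([tx, ty, tz])
    r_pelvis = np.eye(3)
    p_hip = p_pelvis + model.hip_offset

    rz_hf = _rz(hf)
    r_h1 = rz_hf @ _rx(ha)
    r_thigh = r_h1 @ _ry(hr)
    p_knee = p_hip + r_thigh @ np.array([0.0, -model.segments["thigh"].length, 0.0])

    rz_kf = r_thigh @ _rz(-kf)
    r_k1 = rz_kf @ _rx(ka)
    r_shank = r_k1 @ _ry(kr)
    p_ankle = p_knee + r_shank @ np.array([0.0, -model.segments["shank"].length, 0.0])

    rz_df = r_shank @ _rz(df)
    r_foot = rz_df @ _rx(sup)

    ex, ey, ez = np.eye(3)
    axes = {
        "hip_flexion": ez,
        "hip_adduction": rz_hf @ ex,
        "hip_rotation": r_h1 @ ey,
        "knee_flexion": -(r_thigh @ ez),     # flexion is a -Z rotation in the thigh frame
        "knee_adduction": rz_kf @ ex,
        "knee_rotation": r_k1 @ ey,
        "ankle_dorsiflexion": r_shank @ ez,
        "subtalar_supination": rz_df @ ex,
    }
    joint_of = {
        "hip_flexion": p_hip, "hip_adduction": p_hip, "hip_rotation": p_hip,
        "knee_flexion": p_knee, "knee_adduction": p_knee, "knee_rotation": p_knee,
        "ankle_dorsiflexion": p_ankle, "subtalar_supination": p_ankle,
    }
    return ChainState(p_pelvis, p_hip, p_knee, p_ankle,
                      r_pelvis, r_thigh, r_shank, r_foot, axes, joint_of)


_SEG_ORIGIN = {"pelvis": "p_pelvis", "thigh": "p_hip", "shank": "p_knee", "foot": "p_ankle"}
_SEG_ROT = {"pelvis": "r_pelvis", "thigh": "r_thigh", "shank": "r_shank", "foot": "r_foot"}


def marker_positions(model: BodyModel, q: np.ndarray,
                     state: ChainState | None = None) -> dict[str, np.ndarray]:
    """World positions of every mapped marker at pose ``q``."""
    st = state if state is not None else chain_state(model, q)
    out = {}
    for name, (seg, off) in model.markers.items():
        origin = getattr(st, _SEG_ORIGIN[seg])
        rot = getattr(st, _SEG_ROT[seg])
        out[name] = origin + rot @ off
    return out


def segment_com(model: BodyModel, state: ChainState, seg: str) -> np.ndarray:
    """World COM position of a segment at the given chain state."""
    s = model.segments[seg]
    if seg == "pelvis":
        return state.p_pelvis
    if seg == "foot":
        local = np.array([s.com_offset * s.length, -model.foot_com_drop, 0.0])
        return state.p_ankle + state.r_foot @ local
    origin = state.p_hip if seg == "thigh" else state.p_knee
    rot = state.r_thigh if seg == "thigh" else state.r_shank
    return origin + rot @ np.array([0.0, -s.com_offset * s.length, 0.0])


def neutral_q(model: BodyModel, ankle_height: float = 0.05) -> np.ndarray:
    """Upright pose with the ankle at ``ankle_height`` above the ground plane."""
    lt = model.segments["thigh"].length
    ls = model.segments["shank"].length
    ty = ankle_height + lt + ls - model.hip_offset[1]
    q = np.zeros(len(COORDS))
    q[1] = ty
    return q


def pose_dict(q: np.ndarray) -> dict[str, float]:
    """DOF angles of ``q`` (radians) as a name->degrees mapping."""
    return {d: math.degrees(q[3 + i]) for i, d in enumerate(DOFS)}


def rescale(model: BodyModel, factors: dict[str, float]) -> BodyModel:
    """Return a copy with per-segment geometric scale factors applied.

    Lengths, marker offsets and joint offsets scale with their segment;
    masses are participant-derived and unchanged; inertias rescale with
    length squared.
    """
    segments = {}
    for name, seg in model.segments.items():
        f = factors.get(name, 1.0)
        if f <= 0:
            raise ModelError(f"scale factor for {name} must be > 0")
        segments[name] = Segment(name, seg.mass, seg.length * f, seg.com_offset,
                                 seg.inertia * f**2)
    markers = {n: (seg, off * factors.get(seg, 1.0)) for n, (seg, off) in model.markers.items()}
    return replace(
        model,
        segments=segments,
        markers=markers,
        hip_offset=model.hip_offset * factors.get("pelvis", 1.0),
        foot_com_drop=model.foot_com_drop * factors.get("foot", 1.0),
        tibial_plateau_width=model.tibial_plateau_width * factors.get("shank", 1.0),
        scaled=True,
        scale_factors=dict(factors),
    )


def moment_arm(model: BodyModel, muscle: str, dof: str, pose: dict[str, float]) -> float:
    """Signed moment arm (m) of ``muscle`` about ``dof`` at ``pose`` (degrees)."""
    return model.moment_arm(muscle, dof, pose)
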