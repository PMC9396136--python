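"""Tibiofemoral contact force: total axial load and medial/lateral split.

The total compressive force along the tibial long axis is the axial
component of the knee intersegmental force from inverse dynamics plus the
axial pull of every muscle crossing the knee (each muscle's force times its
axial transmission factor).  The medial/lateral split places the condylar
contact points at 25% of the tibial plateau width on either side of the
knee centre and solves the frontal-plane static balance at every time
frame:

    F_med + F_lat = F_tot
    F_med * d - F_lat * d = M_frontal,        d = 0.25 * width

where ``M_frontal`` is the net frontal-plane moment the contacts must
carry: the external (inverse-dynamics) knee ab/adduction moment plus the
frontal moments of the knee-spanning muscles, adduction-positive.  A
negative condyle solution means condylar lift-off; it is clamped to zero
with the whole load on the other compartment and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import IDResult
from .kinematics import N_CYCLE
from .model import BodyModel
from .neuromuscular import ActivationSolution


class ContactError(ValueError):
    pass


@dataclass
class ContactForceCurves:
    """Total/medial/lateral compressive forces on the 101-sample cycle."""

    total: np.ndarray      # N/kg once normalized, raw N before
    medial: np.ndarray
    lateral: np.ndarray
    liftoff: np.ndarray    # bool per sample
    contact_offset: float  # d = 0.25 * tibial width, m
    units: str = "N"

    def __post_init__(self):
        for name in ("total", "medial", "lateral"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (N_CYCLE,):
                raise ContactError(f"{name}: expected {N_CYCLE} samples")
            setattr(self, name, v)
        self.liftoff = np.asarray(self.liftoff, dtype=bool)


def total_knee_contact(model: BodyModel, idr: IDResult,
                       activations: ActivationSolution) -> np.ndarray:
    """Total tibiofemoral compressive force (N), compressive-positive.

    Axial intersegmental force (the femur pressing down the tibia long
    axis) plus every knee-spanning muscle's force scaled by its axial
    transmission factor.
    """
    if activations is None:
        raise ContactError("a static-optimization solution is required")
    axial = -np.einsum("ni,ni->n", idr.f_knee, idr.shank_axis)
    total = axial.copy()
    for name, mus in model.muscles.items():
        if mus.knee_axial_factor:
            total = total + mus.knee_axial_factor * activations.forces[name]
    return total


def knee_frontal_moment(model: BodyModel, idr: IDResult,
                        activations: ActivationSolution,
                        poses: dict[str, np.ndarray]) -> np.ndarray:
    """Net frontal-plane moment carried by the condylar contacts (N m).

    Adduction-positive: the negated internal knee ab/adduction torque from
    inverse dynamics (i.e. the external adduction moment, inertia included)
    plus the frontal moments of the knee-spanning muscles.
    """
    m = -idr.torques["knee_adduction"].copy()
    n = len(m)
    theta = np.asarray(poses["knee_adduction"], dtype=float)
    for name, mus in model.muscles.items():
        coeffs = mus.arms.get("knee_adduction")
        if coeffs is None:
            continue
        r = np.zeros(n)
        for k, ck in enumerate(coeffs):
            r += ck * theta**k
        m = m + r * activations.forces[name]
    return m


def decompose_medial_lateral(f_tot, m_frontal, tibial_width: float):
    """Split a total compressive force into medial/lateral condyle shares.

    Solves the 2x2 static balance with contact points at +/- 0.25 * width
    from the knee centre; negative solutions are clamped to zero (condylar
    lift-off) with the opposite side carrying the whole load.

    Returns ``(f_med, f_lat, liftoff)`` with the same shape as the inputs.
    """
    if tibial_width <= 0:
        raise ContactError("tibial width must be > 0")
    f_tot = np.asarray(f_tot, dtype=float)
    m_frontal = np.asarray(m_frontal, dtype=float)
    d = 0.25 * tibial_width
    f_med = 0.5 * (f_tot + m_frontal / d)
    f_lat = f_tot - f_med
    liftoff = (f_med < 0) | (f_lat < 0)
    f_med_c = np.clip(f_med, 0.0, None)
    f_lat_c = np.clip(f_lat, 0.0, None)
    # after clamping, the unclamped side carries the full load
    f_med_c = np.where(f_lat < 0, f_tot, f_med_c)
    f_lat_c = np.where(f_med < 0, f_tot, f_lat_c)
    if np.ndim(f_tot) == 0:
        return float(f_med_c), float(f_lat_c), bool(liftoff)
    return f_med_c, f_lat_c, liftoff


def contact_curves(total_101: np.ndarray, m_frontal_101: np.ndarray,
                   model: BodyModel, units: str = "N") -> ContactForceCurves:
    """Decompose cycle-normalized total force and frontal moment curves."""
    f_med, f_lat, lift = decompose_medial_lateral(
        np.clip(total_101, 0.0, None), m_frontal_101, model.tibial_plateau_width)
    return ContactForceCurves(np.clip(total_101, 0.0, None), f_med, f_lat, lift,
                              0.25 * model.tibial_plateau_width, units)


def peak_contact_forces(curves: ContactForceCurves) -> dict[str, float]:
    """Peak total and medial compressive forces over the cycle."""
    return {
        "total_contact_peak": float(np.max(curves.total)),
        "medial_contact_peak": float(np.max(curves.medial)),
    }
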