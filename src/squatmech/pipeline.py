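"""End-to-end pipeline: generate/load -> scale -> IK -> ID -> static
optimization -> knee contact -> EMG validation -> group statistics.

One entry point, :func:`run_pipeline`, drives the whole chain from a
:class:`PipelineConfig` and writes a results bundle: scaling reports,
per-trial 101-sample cycle curves, the EMG-vs-static-optimization
validation report, the four metrics tables, SPM results per curve family
and load, and a machine-readable run manifest.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from . import kinematics as kin
from .dynamics import inverse_dynamics, normalize_load, peak_moments
from .knee_contact import (contact_curves, knee_frontal_moment,
                           peak_contact_forces, total_knee_contact)
from .model import DOFS, EMG_MUSCLES, BodyModel, Participant, build_default_model
from .neuromuscular import (emg_bandpass, emg_rms_envelope, normalize_mvc,
                            static_optimization, validate_activations)
from .recording import TrialRecording
from .stats import build_tables, spm_ttest_curves
from .synthetic import CohortSpec, EffectSizes, NoiseLevels, generate_cohort

log = logging.getLogger("squatmech")


class ConfigError(ValueError):
    pass


class GateError(RuntimeError):
    """A processing quality gate (e.g. scaling residual) failed."""


class MissingDataError(FileNotFoundError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str
    synthetic: dict | None = None        # CohortSpec overrides (synthetic mode)
    data_dir: str | None = None          # pre-generated cohort (directory mode)
    seed: int = 0
    alpha: float = 0.05
    welch: bool = False
    perm_spm: bool = False
    strict_emg_band: bool = False
    marker_cutoff_hz: float = 6.0
    upright_threshold_deg: float = 10.0
    emg_band: tuple[float, float] = (100.0, 500.0)
    write_trial_curves: bool = True
    spm_channels: dict = field(default_factory=lambda: {
        "angles": ["hip_flexion", "hip_adduction", "knee_flexion",
                   "knee_adduction", "ankle_dorsiflexion"],
        "moments": ["hip_flexion", "knee_flexion", "knee_adduction",
                    "ankle_dorsiflexion"],
        "contact": ["total", "medial"],
    })

    def __post_init__(self):
        if (self.synthetic is None) == (self.data_dir is None):
            raise ConfigError("exactly one input mode required: "
                              "'synthetic' spec or 'data_dir'")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def cohort_spec(self) -> CohortSpec:
        over = dict(self.synthetic or {})
        eff = EffectSizes(**over.pop("effects", {}))
        noise = NoiseLevels(**over.pop("noise", {}))
        over.setdefault("seed", self.seed)
        if "loads" in over:
            over["loads"] = tuple(over["loads"])
        return CohortSpec(effects=eff, noise=noise, **over)


@dataclass
class TrialResult:
    participant_id: str
    group: str
    load_fraction: float
    trial: int
    angles: kin.CycleCurves
    moments: kin.CycleCurves         # N m/kg
    contact: "object"                # ContactForceCurves, N/kg
    metrics: dict[str, float]
    validation: pd.DataFrame | None
    segmentation: kin.PhaseSegmentation


@dataclass
class PipelineResult:
    config: PipelineConfig
    scaling: dict[str, kin.ScalingReport]
    trials: list[TrialResult]
    metrics: pd.DataFrame
    tables: dict
    spm: dict
    validation: pd.DataFrame
    out_dir: Path


# ---------------------------------------------------------------------------
# per-trial analysis
# ---------------------------------------------------------------------------


def analyze_trial(model: BodyModel, trial: TrialRecording, body_mass: float,
                  barbell_mass: float, config: PipelineConfig | None = None,
                  mvc_rms: dict | None = None) -> TrialResult:
    """Run IK -> ID -> static optimization -> contact on one recording."""
    cfg = config or PipelineConfig(out_dir=".", data_dir=".")
    markers = kin.filter_markers(trial.markers, trial.marker_rate,
                                 cfg.marker_cutoff_hz)
    time, q = kin.inverse_kinematics(model, markers, trial.marker_rate,
                                     prefiltered=True)
    # coordinates get the same low-pass before numerical differentiation:
    # marker filtering alone leaves enough coordinate jitter to corrupt the
    # accelerations the Newton-Euler recursion needs
    q = kin.lowpass(q, trial.marker_rate, cfg.marker_cutoff_hz)
    angles = kin.angles_deg(q)
    seg = kin.segment_cycle(time, angles["knee_flexion"], cfg.upright_threshold_deg)

    grf_force = kin.lowpass(trial.grf_force, trial.marker_rate, cfg.marker_cutoff_hz)
    grf_cop = kin.lowpass(trial.grf_cop, trial.marker_rate, cfg.marker_cutoff_hz)
    idr = inverse_dynamics(model, q, trial.marker_rate, grf_force, grf_cop)
    sol = static_optimization(model, idr.torques, angles)

    total = total_knee_contact(model, idr, sol)
    m_frontal = knee_frontal_moment(model, idr, sol, angles)

    angle_curves = kin.normalize_all(time, angles, seg, "joint_angles", "deg")
    mom_norm = {d: normalize_load(idr.torques[d], body_mass, barbell_mass)
                for d in DOFS}
    moment_curves = kin.normalize_all(time, mom_norm, seg, "joint_moments", "N m/kg")
    total_n = kin.time_normalize(time, normalize_load(total, body_mass, barbell_mass), seg)
    mfront_n = kin.time_normalize(
        time, normalize_load(m_frontal, body_mass, barbell_mass), seg)
    contact = contact_curves(total_n, mfront_n, model, units="N/kg")

    metrics: dict[str, float] = {}
    metrics.update(kin.peak_angles(angle_curves))
    metrics.update(kin.range_of_motion(angle_curves))
    metrics.update(peak_moments(moment_curves))
    metrics.update(peak_contact_forces(contact))

    validation = None
    if trial.emg and (mvc_rms or trial.mvc_rms):
        refs = mvc_rms or trial.mvc_rms
        env = {}
        for muscle, raw in trial.emg.items():
            filt = emg_bandpass(raw, trial.emg_rate, cfg.emg_band,
                                strict=cfg.strict_emg_band)
            times, rms = emg_rms_envelope(filt, trial.emg_rate)
            e = normalize_mvc(times, rms, refs[muscle])
            env[muscle] = kin.time_normalize(e.times, e.values, seg)
        emg_curves = kin.CycleCurves("emg_envelopes", "activation", env)
        so_curves = kin.CycleCurves(
            "so_activations", "activation",
            {m: kin.time_normalize(time, sol.activations[m], seg)
             for m in EMG_MUSCLES})
        validation = validate_activations(emg_curves, so_curves)

    return TrialResult(trial.participant_id, "", trial.load_fraction, 0,
                       angle_curves, moment_curves, contact, metrics,
                       validation, seg)


# ---------------------------------------------------------------------------
# the full chain
# ---------------------------------------------------------------------------


def _load_trial_from_disk(data_dir: Path, entry: dict, mvc_rms: dict) -> TrialRecording:
    try:
        markers, rate, _ = sio.read_trc(data_dir / entry["trc"])
        _, force, cop = sio.read_grf(data_dir / entry["grf"])
        _, emg = sio.read_emg(data_dir / entry["emg"])
    except FileNotFoundError as exc:
        raise MissingDataError(str(exc)) from exc
    return TrialRecording(
        participant_id=entry["participant"], load_fraction=entry["load_fraction"],
        markers=markers, marker_rate=rate, grf_force=force, grf_cop=cop,
        emg=emg, emg_rate=1000.0, mvc_rms=mvc_rms)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis chain and write the results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        spec = config.cohort_spec()
        data_dir = out / "cohort"
        log.info("generating synthetic cohort (seed=%d) in %s", spec.seed, data_dir)
        manifest = generate_cohort(spec, data_dir)
    else:
        data_dir = Path(config.data_dir)
        if not (data_dir / "manifest.json").exists():
            raise MissingDataError(f"no manifest.json in {data_dir}")
        manifest = sio.read_manifest(data_dir / "manifest.json")

    scaling: dict[str, kin.ScalingReport] = {}
    models: dict[str, BodyModel] = {}
    participants: dict[str, dict] = {}
    for pinfo in manifest["participants"]:
        part = Participant(pinfo["id"], pinfo["mass_kg"], pinfo["height_m"],
                           pinfo["valgus_angle_deg"], pinfo["one_rm_kg"],
                           pinfo["group"])
        markers, rate, _ = sio.read_trc(data_dir / pinfo["static_trc"])
        n = len(next(iter(markers.values())))
        static = TrialRecording(part.id, 0.0, markers, rate,
                                np.zeros((n, 3)), np.zeros((n, 3)))
        model = build_default_model(part)
        scaled, report = kin.scale_model(model, static)
        if not report.passed:
            raise GateError(
                f"scaling gate failed for {part.id}: RMS {report.rms_error:.4f} m "
                f"(gate {report.rms_gate}), max {report.max_error:.4f} m "
                f"(gate {report.max_gate})")
        scaling[part.id] = report
        models[part.id] = scaled
        participants[part.id] = pinfo
        log.info("scaled %s: RMS %.4f m, max %.4f m", part.id,
                 report.rms_error, report.max_error)

    trials: list[TrialResult] = []
    rows = []
    val_frames = []
    curves_dir = out / "curves"
    if config.write_trial_curves:
        curves_dir.mkdir(exist_ok=True)
    for entry in manifest["trials"]:
        pid = entry["participant"]
        pinfo = participants[pid]
        rec = _load_trial_from_disk(data_dir, entry, pinfo.get("mvc_rms") or {})
        tr = analyze_trial(models[pid], rec, pinfo["mass_kg"],
                           entry["barbell_mass_kg"], config)
        tr.group = entry["group"]
        tr.trial = entry["trial"]
        trials.append(tr)
        for metric, value in tr.metrics.items():
            rows.append({"participant_id": pid, "group": entry["group"],
                         "load": entry["load_fraction"], "trial": entry["trial"],
                         "metric": metric, "value": value})
        if tr.validation is not None:
            v = tr.validation.reset_index()
            v.insert(0, "participant_id", pid)
            v.insert(1, "load", entry["load_fraction"])
            v.insert(2, "trial", entry["trial"])
            val_frames.append(v)
        if config.write_trial_curves:
            stem = f"{pid}_L{int(round(entry['load_fraction'] * 100)):02d}_T{entry['trial']}"
            sio.write_cycle_curves(curves_dir / f"{stem}_angles.csv",
                                   tr.angles.curves, "deg",
                                   "joint angles, squat cycle 0-100%")
            sio.write_cycle_curves(curves_dir / f"{stem}_moments.csv",
                                   tr.moments.curves, "N m/kg",
                                   "net joint moments / (body+barbell) mass")
            sio.write_cycle_curves(
                curves_dir / f"{stem}_contact.csv",
                {"total": tr.contact.total, "medial": tr.contact.medial,
                 "lateral": tr.contact.lateral,
                 "liftoff": tr.contact.liftoff.astype(float)},
                "N/kg", "tibiofemoral contact forces")

    per_trial = pd.DataFrame(rows)
    metrics = (per_trial.groupby(
        ["participant_id", "group", "load", "metric"], as_index=False)["value"]
        .mean())
    tables = build_tables(metrics, alpha=config.alpha, welch=config.welch)

    spm_method = "perm" if config.perm_spm else "rft"
    spm_results: dict[str, dict] = {}
    loads = sorted({t.load_fraction for t in trials})
    for family, channels in config.spm_channels.items():
        for channel in channels:
            for load in loads:
                key = f"{family}/{channel}/L{int(round(load * 100)):02d}"
                groups = {}
                for gname in ("valgus", "normal"):
                    sel = [t for t in trials
                           if t.group == gname and t.load_fraction == load]
                    by_pid: dict[str, list] = {}
                    for t in sel:
                        curve = (getattr(t.contact, channel) if family == "contact"
                                 else (t.angles if family == "angles" else t.moments)[channel])
                        by_pid.setdefault(t.participant_id, []).append(curve)
                    groups[gname] = np.array([np.mean(cs, axis=0)
                                              for cs in by_pid.values()])
                res = spm_ttest_curves(groups["valgus"], groups["normal"],
                                       alpha=config.alpha, method=spm_method,
                                       n_perm=2000, rng=config.seed)
                spm_results[key] = res

    validation = (pd.concat(val_frames, ignore_index=True)
                  if val_frames else pd.DataFrame())

    _write_bundle(out, config, manifest, scaling, metrics, tables,
                  spm_results, validation)
    return PipelineResult(config, scaling, trials, metrics, tables,
                          spm_results, validation, out)


def _metric_units(name: str) -> str:
    if name.endswith("_contact_peak"):
        return "N/kg"
    if name.endswith("_moment"):
        return "N m/kg"
    return "deg"


def _write_bundle(out: Path, config: PipelineConfig, manifest, scaling,
                  metrics, tables, spm_results, validation) -> None:
    pd.DataFrame([
        {"participant_id": pid, "rms_error_m": r.rms_error,
         "max_error_m": r.max_error, "passed": r.passed,
         **{f"scale_{k}": v for k, v in r.factors.items()}}
        for pid, r in scaling.items()
    ]).to_csv(out / "scaling_reports.csv", index=False, float_format="%.6f")

    metrics = metrics.copy()
    metrics["units"] = [_metric_units(m) for m in metrics["metric"]]
    metrics.to_csv(out / "participant_metrics.csv", index=False,
                   float_format="%.6f")
    for name, table in tables.items():
        table.to_csv(out / f"table_{name}.csv")
        table.pvalues.to_csv(out / f"table_{name}_pvalues.csv",
                             float_format="%.6g")
    if len(validation):
        validation.to_csv(out / "emg_validation.csv", index=False,
                          float_format="%.6f")

    spm_dir = out / "spm"
    spm_dir.mkdir(exist_ok=True)
    summary = {}
    for key, res in spm_results.items():
        fname = key.replace("/", "_")
        sio.write_cycle_curves(spm_dir / f"{fname}_t.csv",
                               {"t": res.t_curve}, "t-statistic",
                               f"SPM t-curve, threshold {res.t_star:.3f}")
        summary[key] = res.to_dict()
    sio.write_manifest(spm_dir / "summary.json", summary)

    sio.write_manifest(out / "run_manifest.json", {
        "seed": config.seed,
        "alpha": config.alpha,
        "welch": config.welch,
        "spm_method": "perm" if config.perm_spm else "rft",
        "n_participants": len(manifest["participants"]),
        "n_trials": len(manifest["trials"]),
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "spm_channels"},
    })
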