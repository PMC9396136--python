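"""Readers and writers for the text formats the pipeline exchanges.

TRC (Track Row Column) is the de-facto tab-separated motion-capture marker
format: two header lines of acquisition metadata, a marker-name row, an
X/Y/Z component row, then one row per frame of ``Frame#  Time  x y z ...``.
Units are metres throughout (the header says so).  GRF and EMG streams are
plain CSV with a one-line header naming columns and units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_trc(path, markers: dict[str, np.ndarray], rate: float, start_time: float = 0.0) -> None:
    """Write marker trajectories (name -> (n_frames, 3) metres) to TRC."""
    names = list(markers)
    n = len(next(iter(markers.values())))
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path.name}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{rate:g}\t{rate:g}\t{n}\t{len(names)}\tm\t{rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t\t\n")
        comp = "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1))
        fh.write("\t\t" + comp + "\n")
        data = np.hstack([np.asarray(markers[m]) for m in names])
        for i in range(n):
            t = start_time + i / rate
            row = "\t".join(format(v, ".8f") for v in data[i])
            fh.write(f"{i + 1}\t{t:.6f}\t{row}\n")


def read_trc(path) -> tuple[dict[str, np.ndarray], float, np.ndarray]:
    """Read a TRC file -> (markers, rate, time vector)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    meta = lines[2].split("\t")
    rate = float(meta[0])
    names = [s for s in lines[3].split("\t")[2:] if s]
    rows = [ln.split("\t") for ln in lines[5:] if ln.strip()]
    arr = np.array([[float(v) for v in r[1:2 + 3 * len(names)]] for r in rows])
    time = arr[:, 0]
    markers = {m: arr[:, 1 + 3 * i: 4 + 3 * i] for i, m in enumerate(names)}
    return markers, rate, time


def write_grf(path, time: np.ndarray, force: np.ndarray, cop: np.ndarray) -> None:
    df = pd.DataFrame({
        "time_s": time,
        "Fx_N": force[:, 0], "Fy_N": force[:, 1], "Fz_N": force[:, 2],
        "COPx_m": cop[:, 0], "COPy_m": cop[:, 1], "COPz_m": cop[:, 2],
    })
    df.to_csv(path, index=False, float_format="%.8f")


def read_grf(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy()
    force = df[["Fx_N", "Fy_N", "Fz_N"]].to_numpy()
    cop = df[["COPx_m", "COPy_m", "COPz_m"]].to_numpy()
    return time, force, cop


def write_emg(path, time: np.ndarray, channels: dict[str, np.ndarray]) -> None:
    df = pd.DataFrame({"time_s": time, **{f"{k}_V": v for k, v in channels.items()}})
    df.to_csv(path, index=False, float_format="%.8f")


def read_emg(path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    df = pd.read_csv(path)
    time = df["time_s"].to_numpy()
    channels = {c[:-2]: df[c].to_numpy() for c in df.columns if c.endswith("_V")}
    return time, channels


def write_manifest(path, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_cycle_curves(path, curves: dict[str, np.ndarray], units: str, note: str = "") -> None:
    """Write 101-sample cycle curves as CSV with a unit-bearing header."""
    df = pd.DataFrame({"cycle_pct": np.arange(101)})
    for name, vals in curves.items():
        df[f"{name} [{units}]"] = vals
    with open(path, "w", newline="") as fh:
        if note:
            fh.write(f"# {note}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
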