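"""Synchronized trial containers shared by the generator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class RecordingError(ValueError):
    pass


@dataclass
class TrialRecording:
    """Markers + GRF + EMG for one squat (or static) trial.

    All streams start at t = 0 and share one duration.  Marker trajectories
    are metres at ``marker_rate`` Hz; GRF is newtons with COP in metres at
    the same rate; EMG channels are volts at ``emg_rate`` (1,000 Hz in the
    study design).
    """

    participant_id: str
    load_fraction: float
    markers: dict[str, np.ndarray]           # name -> (n, 3)
    marker_rate: float
    grf_force: np.ndarray                    # (n, 3)
    grf_cop: np.ndarray                      # (n, 3)
    emg: dict[str, np.ndarray] = field(default_factory=dict)   # muscle -> (m,)
    emg_rate: float = 1000.0
    mvc_rms: dict[str, float] = field(default_factory=dict)
    ground_truth: "GroundTruth | None" = None

    def __post_init__(self):
        n = {len(v) for v in self.markers.values()}
        if len(n) != 1:
            raise RecordingError("marker trajectories have inconsistent lengths")
        n = n.pop()
        if len(self.grf_force) != n or len(self.grf_cop) != n:
            raise RecordingError("GRF stream not time-aligned with markers")
        if np.any(self.grf_force[:, 1] < -1e-9):
            raise RecordingError("vertical GRF must be non-negative")
        dur = n / self.marker_rate
        for name, ch in self.emg.items():
            if abs(len(ch) / self.emg_rate - dur) > 2.0 / self.emg_rate:
                raise RecordingError(f"EMG channel {name!r} duration mismatch")

    @property
    def n_frames(self) -> int:
        return len(self.grf_force)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.marker_rate

    @property
    def emg_time(self) -> np.ndarray:
        m = len(next(iter(self.emg.values()))) if self.emg else 0
        return np.arange(m) / self.emg_rate


@dataclass
class GroundTruth:
    """Generating quantities attached to a synthetic trial for recovery tests."""

    q: np.ndarray                       # (n, 11) generalized coords, angles rad
    torques: dict[str, np.ndarray]      # DOF -> (n,) net joint moment, N m
    activations: dict[str, np.ndarray]  # muscle -> (n,) in [0, 1]
    grf_force: np.ndarray               # (n, 3) noise-free
    grf_cop: np.ndarray                 # (n, 3) noise-free
    deepest_index: int
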