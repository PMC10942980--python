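"""Reading and writing the pipeline's CSV formats, configuration, and logging.

All streams are plain CSV with a ``time_s`` first column (seconds, strictly
increasing, uniform step).  Streams are *unaligned* on disk — the IMUs start
recording after motion capture — and are synchronized downstream.

Column conventions
------------------
markers.csv
    ``time_s`` then ``<marker>_{x,y,z}`` in metres, lab frame
    (X = direction of progression, Z = up, Y = left; right-handed).
forces.csv
    ``time_s, f_x, f_y, f_z`` in newtons (f_x anterior +, f_z vertical +up).
imu_<segment>.csv
    ``time_s, q_w, q_x, q_y, q_z`` (sensor-to-global unit quaternion),
    ``gyro_{x,y,z}`` (deg/s), ``acc_{x,y,z}`` (m/s^2).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("overstride")

__all__ = [
    "TrialTable",
    "ParticipantAnthro",
    "PipelineConfig",
    "read_trial",
    "write_trial",
    "write_stride_records",
    "read_stride_records",
    "load_config",
]

_MANDATORY = {
    "forces": ["f_x", "f_y", "f_z"],
    "imu": ["q_w", "q_x", "q_y", "q_z"],
    "markers": [],  # marker sets vary; only time_s is mandatory
}

_QUAT_COLS = ["q_w", "q_x", "q_y", "q_z"]


@dataclasses.dataclass
class TrialTable:
    """A uniformly sampled multichannel time series.

    Attributes
    ----------
    data : pandas.DataFrame
        One column per channel, excluding time.
    sample_rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in this stream's own clock, seconds.
    kind : str
        One of ``{"markers", "forces", "imu"}`` (or ``"derived"``).
    """

    data: pd.DataFrame
    sample_rate: float
    t0: float = 0.0
    kind: str = "derived"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds (this stream's clock)."""
        return self.t0 + np.arange(len(self.data)) / self.sample_rate

    @property
    def duration(self) -> float:
        return (len(self.data) - 1) / self.sample_rate

    def __len__(self) -> int:
        return len(self.data)

    def channel(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def copy_with(self, data: pd.DataFrame | None = None,
                  t0: float | None = None) -> "TrialTable":
        return TrialTable(
            data=self.data.copy() if data is None else data,
            sample_rate=self.sample_rate,
            t0=self.t0 if t0 is None else t0,
            kind=self.kind,
        )


@dataclasses.dataclass
class ParticipantAnthro:
    """Anthropometry needed to normalize metrics.

    leg_length is the static-pose greater-trochanter to lateral-malleolus
    distance; segment lengths are thigh (hip-knee), shank (knee-ankle) and
    foot (heel-toe), all in metres.
    """

    participant_id: str
    mass: float
    leg_length: float
    thigh_length: float
    shank_length: float
    foot_length: float

    def __post_init__(self) -> None:
        for name in ("mass", "leg_length", "thigh_length", "shank_length",
                     "foot_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.leg_length > self.thigh_length + self.shank_length + 0.05:
            raise ValueError(
                "leg_length exceeds thigh + shank lengths by more than 5 cm"
            )

    @property
    def body_weight(self) -> float:
        """Body weight in newtons."""
        return self.mass * 9.81


@dataclasses.dataclass
class PipelineConfig:
    """Processing parameters for the analysis pipeline."""

    marker_cutoff_hz: float = 10.0
    force_cutoff_hz: float = 50.0
    fc_threshold_n: float = 20.0
    min_stance_s: float = 0.1
    min_flight_s: float = 0.05
    speed_filter_fraction: float = 0.05
    tm_keep_last_strides: int = 15
    analysis_rate_hz: float = 200.0
    max_lag_s: float = 0.25
    sync_segment: str = "all"  # one segment name, or "all" to average
    # spans the calibration maneuver; ends early enough that no running
    # content enters either stream's window for delays up to max_lag_s
    sync_window_s: tuple = (0.8, 4.3)
    sf_levels: tuple = (75, 80, 85, 90, 95)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold_n <= 0:
            raise ValueError("fc_threshold_n must be > 0")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a PipelineConfig from a YAML file."""
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def _infer_rate(t: np.ndarray) -> float:
    if len(t) < 2:
        raise ValueError("need at least 2 samples to infer sample rate")
    dt = np.diff(t)
    step = dt[0]
    if step <= 0:
        raise ValueError("time must be strictly increasing at index 1")
    bad = np.nonzero(np.abs(dt - step) > 1e-6 * max(abs(step), 1e-12) + 1e-9)[0]
    if bad.size:
        raise ValueError(f"non-uniform sampling at index {bad[0] + 2 - 1}")
    return 1.0 / step


def read_trial(path: str | Path, kind: str) -> TrialTable:
    """Read a markers/forces/imu CSV into a :class:`TrialTable`.

    The first column must be ``time_s``, strictly increasing with a uniform
    step (1e-6 relative tolerance).  Quaternion columns are renormalized to
    unit length on load; no other values are mutated.

    Raises
    ------
    ValueError
        If sampling is non-uniform (names the first bad index) or mandatory
        columns for ``kind`` are missing (lists them).
    """
    if kind not in _MANDATORY:
        raise ValueError(f"kind must be one of {sorted(_MANDATORY)}")
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError("first column must be time_s")
    missing = [c for c in _MANDATORY[kind] if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory columns: {missing}")
    t = df["time_s"].to_numpy(dtype=float)
    rate = _infer_rate(t)
    data = df.drop(columns=["time_s"])
    if data.isna().any().any():
        raise ValueError("NaN values in loaded table")
    if kind == "imu":
        q = data[_QUAT_COLS].to_numpy(dtype=float)
        norm = np.linalg.norm(q, axis=1)
        if np.any(norm == 0):
            raise ValueError("zero quaternion in IMU table")
        data[_QUAT_COLS] = q / norm[:, None]
    return TrialTable(data=data, sample_rate=float(round(rate, 9)),
                      t0=float(t[0]), kind=kind)


def write_trial(table: TrialTable, path: str | Path) -> None:
    """Write a TrialTable to CSV (inverse of :func:`read_trial`)."""
    out = table.data.copy()
    out.insert(0, "time_s", table.time)
    out.to_csv(path, index=False, float_format="%.10g")


# Stable column order for stride-record CSVs.
STRIDE_COLUMNS = [
    "participant_id", "condition", "stride_index",
    "fc_time", "to_time", "next_fc_time",
    "theta_thigh_fc", "theta_shank_fc", "theta_foot_fc",
    "theta_thigh_imu_fc", "theta_shank_imu_fc", "theta_foot_imu_fc",
    "overstriding_m", "overstriding_norm", "pbf_bw",
    "stride_frequency", "duty_cycle", "speed",
]


def write_stride_records(records, path: str | Path) -> None:
    """Write stride records to CSV with a stable column order.

    ``records`` may be a list of dict-like/dataclass records or a DataFrame.
    An empty list writes a header-only file.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [dataclasses.asdict(r) if dataclasses.is_dataclass(r) else dict(r)
                for r in records]
        df = pd.DataFrame(rows, columns=STRIDE_COLUMNS if not rows else None)
    cols = [c for c in STRIDE_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df = df.reindex(columns=cols)
    df.to_csv(path, index=False, float_format="%.12g")


def read_stride_records(path: str | Path) -> pd.DataFrame:
    """Read a stride-record CSV written by :func:`write_stride_records`."""
    return pd.read_csv(path)
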