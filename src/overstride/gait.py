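"""Gait events from ground reaction force and per-stride metrics.

Foot contact (FC) is the instant the vertical GRF first exceeds a 20 N
threshold; toe-off (TO) the instant it falls back below.  Crossing times
are linearly interpolated between force samples, and candidate events are
debounced: stance must last at least ``min_stance`` and flight at least
``min_flight`` so threshold chatter does not produce spurious strides.

A stride spans successive foot contacts of the instrumented (left) leg.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd

logger = logging.getLogger("overstride")

__all__ = [
    "StrideEvents",
    "StrideRecord",
    "detect_foot_contacts",
    "peak_braking_force",
    "stride_frequency_and_duty",
    "select_strides",
]


@dataclasses.dataclass
class StrideEvents:
    """Foot-contact and toe-off times (seconds, reference clock).

    Strides are the half-open intervals [FC_k, FC_{k+1}); each complete
    stride contains exactly one toe-off with FC_k < TO_k < FC_{k+1}.
    """

    fc_times: np.ndarray
    to_times: np.ndarray

    def __post_init__(self) -> None:
        self.fc_times = np.asarray(self.fc_times, dtype=float)
        self.to_times = np.asarray(self.to_times, dtype=float)
        if np.any(np.diff(self.fc_times) <= 0):
            raise ValueError("fc_times must be strictly increasing")

    @property
    def n_strides(self) -> int:
        return max(0, len(self.fc_times) - 1)

    def stride_bounds(self):
        """(FC_k, TO_k, FC_{k+1}) per complete stride."""
        out = []
        for k in range(self.n_strides):
            fc0, fc1 = self.fc_times[k], self.fc_times[k + 1]
            to = self.to_times[(self.to_times > fc0) & (self.to_times < fc1)]
            if len(to) != 1:
                raise ValueError(
                    f"stride {k} has {len(to)} toe-offs (expected 1)")
            out.append((fc0, float(to[0]), fc1))
        return out


@dataclasses.dataclass
class StrideRecord:
    """One stride's extracted metrics (columns of stride_records.csv)."""

    participant_id: str
    condition: str
    stride_index: int
    fc_time: float
    to_time: float
    next_fc_time: float
    theta_thigh_fc: float
    theta_shank_fc: float
    theta_foot_fc: float
    theta_thigh_imu_fc: float
    theta_shank_imu_fc: float
    theta_foot_imu_fc: float
    overstriding_m: float
    overstriding_norm: float
    pbf_bw: float
    stride_frequency: float
    duty_cycle: float
    speed: float


def _cross_time(t: np.ndarray, y: np.ndarray, i: int, thresh: float) -> float:
    """Linear-interpolated time where y crosses thresh between i and i+1."""
    y0, y1 = y[i], y[i + 1]
    if y1 == y0:
        return float(t[i])
    return float(t[i] + (thresh - y0) / (y1 - y0) * (t[i + 1] - t[i]))


def detect_foot_contacts(vertical_grf: np.ndarray, sample_rate: float,
                         t0: float = 0.0, threshold: float = 20.0,
                         min_stance: float = 0.1,
                         min_flight: float = 0.05) -> StrideEvents:
    """Detect FC/TO from the vertical GRF threshold rule.

    Candidate crossings shorter than the debounce windows are merged:
    a sub-``min_flight`` dip stays in stance, a sub-``min_stance`` bump
    stays in flight.  Returns empty events (with a warning) if the trace
    never crosses the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    y = np.asarray(vertical_grf, dtype=float)
    t = t0 + np.arange(len(y)) / sample_rate
    above = y > threshold
    change = np.nonzero(np.diff(above.astype(int)))[0]
    if change.size == 0:
        warnings.warn("vertical GRF never crosses threshold; no events")
        return StrideEvents(fc_times=np.array([]), to_times=np.array([]))
    # build raw intervals of 'above threshold' state
    ups = [i for i in change if not above[i]]     # below -> above (FC)
    downs = [i for i in change if above[i]]       # above -> below (TO)
    raw = []
    for i in ups:
        j = next((d for d in downs if d > i), None)
        raw.append((_cross_time(t, y, i, threshold),
                    _cross_time(t, y, j, threshold) if j is not None
                    else t[-1]))
    # debounce: merge stances separated by a flight shorter than min_flight
    merged = []
    for fc, to in raw:
        if merged and fc - merged[-1][1] < min_flight:
            merged[-1] = (merged[-1][0], to)
        else:
            merged.append((fc, to))
    # drop stances shorter than min_stance (chatter bumps)
    stances = [(fc, to) for fc, to in merged if to - fc >= min_stance]
    if not stances:
        warnings.warn("no stance phase passed debouncing")
        return StrideEvents(fc_times=np.array([]), to_times=np.array([]))
    fc_times = np.array([s[0] for s in stances])
    to_times = np.array([s[1] for s in stances])
    return StrideEvents(fc_times=fc_times, to_times=to_times)


def peak_braking_force(ap_grf: np.ndarray, time: np.ndarray,
                       stance: tuple, body_weight: float) -> float:
    """Peak posterior (braking) GRF over a stance, in body weights.

    The anterior-posterior channel is positive-anterior; braking is its
    negative part.  Returns 0 with a warning if the stance contains no
    posterior force.
    """
    if body_weight <= 0:
        raise ValueError("body_weight must be > 0")
    fc, to = stance
    time = np.asarray(time, dtype=float)
    if fc < time[0] or to > time[-1]:
        raise ValueError("stance outside series support")
    sel = (time >= fc) & (time <= to)
    seg = np.asarray(ap_grf, dtype=float)[sel]
    m = -seg.min()
    if m <= 0:
        warnings.warn("no posterior force in stance; PBF set to 0")
        return 0.0
    return float(m / body_weight)


def stride_frequency_and_duty(events: StrideEvents) -> pd.DataFrame:
    """Per-stride stride frequency (strides/min) and duty cycle.

    SF_k = 60 / (FC_{k+1} - FC_k); duty_k = (TO_k - FC_k) / stride time.
    Returns an empty frame when fewer than two foot contacts exist.
    """
    rows = []
    if events.n_strides >= 1:
        for k, (fc0, to, fc1) in enumerate(events.stride_bounds()):
            T = fc1 - fc0
            rows.append({"stride_index": k, "fc_time": fc0, "to_time": to,
                         "next_fc_time": fc1, "stride_frequency": 60.0 / T,
                         "duty_cycle": (to - fc0) / T})
    return pd.DataFrame(rows, columns=["stride_index", "fc_time", "to_time",
                                       "next_fc_time", "stride_frequency",
                                       "duty_cycle"])


def select_strides(records: pd.DataFrame, condition: str,
                   keep_last: int = 15,
                   speed_fraction: float = 0.05) -> pd.DataFrame:
    """Apply the study's stride-selection rules.

    Treadmill conditions: keep the final ``keep_last`` strides of the trial
    (all, with a warning, if fewer exist).  Overground: keep strides whose
    speed is within ``speed_fraction`` of the trial's median speed.
    """
    df = records[records["condition"] == condition]
    if condition == "OG":
        med = df["speed"].median()
        keep = np.abs(df["speed"] - med) <= speed_fraction * med
        return df[keep]
    if len(df) < keep_last:
        warnings.warn(
            f"only {len(df)} strides in {condition}; expected >= {keep_last}")
        return df
    return df.iloc[-keep_last:]
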