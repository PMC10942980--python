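"""Sagittal segment angles, leg length, and overstriding from markers.

Marker-based kinematics are the ground-truth arm of the analysis.  Segment
angles are measured in the plane of progression against the lab global
frame: thigh and shank against vertical (positive when the distal end is
ahead of the proximal end), foot against horizontal (positive toe-above-heel
= rear-foot strike).  Overstriding is the forward horizontal distance from
the greater-trochanter marker to the lateral-malleolus marker at foot
contact, normalized by leg length.

Landmark conventions: knee center = midpoint of the femoral epicondyle
markers; ankle center = midpoint of the malleoli; foot vector = calcaneus
to second-metatarsal head.  Angles use anatomical-marker segment vectors
(cluster plates exist only to co-locate the IMUs).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .dataio import TrialTable

__all__ = [
    "OverstridingValue",
    "segment_angle_from_markers",
    "overstriding_from_markers",
    "leg_length_from_static",
    "forward_direction",
    "marker_xyz",
]

_RAD2DEG = 180.0 / np.pi


@dataclasses.dataclass
class OverstridingValue:
    """Overstriding at one foot contact: raw metres and leg-length units."""

    raw: float
    normalized: float


def marker_xyz(table: TrialTable, marker: str) -> np.ndarray:
    """Return an (n, 3) array for ``<marker>_{x,y,z}`` columns."""
    cols = [f"{marker}_{ax}" for ax in "xyz"]
    missing = [c for c in cols if c not in table.data.columns]
    if missing:
        raise ValueError(f"missing marker columns: {missing}")
    return table.data[cols].to_numpy(dtype=float)


def _horizontal_components(v: np.ndarray, forward: np.ndarray):
    """Forward and vertical components of 3D vectors (lab Z is up)."""
    fwd = np.asarray(forward, dtype=float)
    fwd = fwd / np.linalg.norm(fwd)
    comp_fwd = v[..., 0] * fwd[0] + v[..., 1] * fwd[1]
    comp_up = v[..., 2]
    return comp_fwd, comp_up


def segment_angle_from_markers(proximal: np.ndarray, distal: np.ndarray,
                               reference: str,
                               forward=(1.0, 0.0)) -> np.ndarray:
    """Sagittal segment angle series in degrees.

    ``reference="vertical"`` (thigh/shank): angle between the proximal->
    distal vector and straight down, positive when the distal end is ahead.
    ``reference="horizontal"`` (foot, heel->toe): elevation of the vector
    above horizontal, positive toe-above-heel (rear-foot strike).
    """
    v = np.asarray(distal, dtype=float) - np.asarray(proximal, dtype=float)
    norms = np.linalg.norm(v, axis=-1)
    bad = np.nonzero(norms < 1e-12)[0]
    if bad.size:
        raise ValueError(f"zero-length segment vector at frame {bad[0]}")
    comp_fwd, comp_up = _horizontal_components(v, forward)
    if reference == "vertical":
        theta = np.arctan2(comp_fwd, -comp_up)
    elif reference == "horizontal":
        theta = np.arctan2(comp_up, comp_fwd)
    else:
        raise ValueError("reference must be 'vertical' or 'horizontal'")
    return theta * _RAD2DEG


def overstriding_from_markers(trochanter: np.ndarray,
                              lateral_malleolus: np.ndarray,
                              time: np.ndarray, fc_time: float,
                              leg_length: float,
                              forward=(1.0, 0.0)) -> OverstridingValue:
    """Overstriding at one FC instant (linear interpolation to ``fc_time``).

    raw = forward component of (malleolus - trochanter) at FC, metres;
    positive = foot ahead of hip.  normalized = raw / leg_length.
    """
    if leg_length <= 0:
        raise ValueError("leg_length must be > 0")
    time = np.asarray(time, dtype=float)
    if not (time[0] <= fc_time <= time[-1]):
        raise ValueError(f"FC time {fc_time} outside series support")
    d = np.asarray(lateral_malleolus, float) - np.asarray(trochanter, float)
    comp_fwd, _ = _horizontal_components(d, forward)
    raw = float(np.interp(fc_time, time, comp_fwd))
    return OverstridingValue(raw=raw, normalized=raw / leg_length)


def leg_length_from_static(static: TrialTable,
                           trochanter: str = "trochanter",
                           malleolus: str = "lat_malleolus") -> float:
    """Leg length = mean 3D trochanter-to-lateral-malleolus distance.

    Requires a standing trial of at least 0.5 s.
    """
    if static.duration < 0.5:
        raise ValueError("static trial must be at least 0.5 s")
    p = marker_xyz(static, trochanter)
    q = marker_xyz(static, malleolus)
    return float(np.mean(np.linalg.norm(q - p, axis=1)))


def forward_direction(reference_marker: np.ndarray,
                      min_displacement: float = 0.3) -> np.ndarray:
    """Unit horizontal progression direction from net marker displacement.

    Uses the net horizontal displacement of a trunk marker over a stride
    window.  Raises for treadmill-like (stationary) data, in which case the
    caller should fall back to the lab +X convention.
    """
    p = np.asarray(reference_marker, dtype=float)
    d = p[-1, :2] - p[0, :2]
    norm = np.linalg.norm(d)
    if norm <= min_displacement:
        raise ValueError(
            "net horizontal displacement below threshold; "
            "use the lab +X convention for treadmill data")
    return d / norm
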