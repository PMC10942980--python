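"""Synthetic running-study generator with full ground truth.

Emulates the study design end to end: ten runners, five metronome-paced
30-s treadmill (TM) trials at stride frequencies 75-95 strides/min that
systematically modulate overstriding, one comfortable-speed overground
(OG) trial, and a standing static trial.  Every trial produces mutually
consistent marker (200 Hz), force (2000 Hz) and IMU (120 Hz) streams plus
the exact per-frame and per-stride truth, so each pipeline stage can be
validated against known values.

The skeleton is planar (sagittal-only): segment angles drive markers by
forward kinematics, so marker-derived overstriding satisfies the geometric
identity OS = L_t sin(theta_thigh) + L_s sin(theta_shank) exactly on
noiseless data.  The IMU streams corrupt the true segment rotation with a
constant mounting misalignment, low-frequency soft-tissue-like wobble,
white orientation noise, heading drift about gravity, and a start delay of
90-180 ms; a calibration maneuver (hard step then forward/backward leg
swing) is prepended for synchronization.  The braking-force peak of each
stance is generated from a linear model on the standardized foot-contact
angles with participant-level random intercepts, which is what the mixed
models downstream are asked to recover.

True foot-contact times fall exactly on the 200 Hz marker grid (stride
periods are rounded to whole marker frames), so FC-instant interpolation
of marker channels is exact and commanded stride frequencies are
reproduced to better than 0.2 strides/min.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.signal
from scipy.spatial.transform import Rotation

from .dataio import ParticipantAnthro, TrialTable
from .imu import OrientationSeries

__all__ = [
    "SimConfig",
    "TrialTruth",
    "simulate_lmm_dataset",
    "simulate_stride_table",
    "simulate_participant",
    "simulate_imu",
    "simulate_grf",
    "simulate_study",
    "write_study",
]

GRAV = 9.81


@dataclasses.dataclass
class SimConfig:
    """Generator parameters.  Defaults are the emulated study conditions."""

    n_participants: int = 10
    seed: int = 0
    # anthropometry
    leg_length_mean: float = 0.89
    leg_length_sd: float = 0.04
    mass_mean: float = 71.8
    mass_sd: float = 15.3
    thigh_fraction_mean: float = 0.5
    thigh_fraction_sd: float = 0.015
    foot_length: float = 0.24
    # protocol
    sf_levels: tuple = (75, 80, 85, 90, 95)
    tm_speed: float = 3.0
    tm_duration: float = 30.0     # running-phase seconds per TM trial
    og_duration: float = 60.0     # desk-scale default; study used 300 s
    og_speed_mean: float = 2.9
    og_speed_sd: float = 0.27
    og_sf_mean: float = 81.0
    og_sf_sd: float = 3.5
    # trial timeline (s): standing, calibration maneuver, blend-in
    stand_duration: float = 1.5
    maneuver_duration: float = 3.0
    lead_in: float = 1.0
    # sampling rates (Hz)
    marker_rate: float = 200.0
    force_rate: float = 2000.0
    imu_rate: float = 120.0
    # foot-contact angle means (deg): value at SF 75 minus slope per level
    thigh_fc_base: float = 24.0
    thigh_fc_slope: float = 1.0
    shank_fc_base: float = 8.0
    shank_fc_slope: float = 1.1
    foot_fc_base: float = 16.0
    foot_fc_slope: float = 2.25
    participant_angle_sd: float = 2.0
    stride_angle_sd: float = 0.5    # independent per-segment, per-stride
    stride_common_sd: float = 1.0   # shared across segments per stride
    stride_period_jitter_s: float = 0.004
    # duty cycle (contact time / stride time)
    duty_base: float = 0.30
    duty_slope: float = 0.01
    duty_participant_sd: float = 0.02
    duty_stride_sd: float = 0.008
    # ground reaction force
    vertical_peak_bw: float = 2.5
    vertical_peak_cv: float = 0.03
    fc_threshold_n: float = 20.0
    force_noise_n: float = 0.5
    # braking-peak generative model (standardized units)
    b_thigh: float = 0.35
    b_shank: float = 0.35
    b_foot: float = 0.15
    sigma_b: float = 0.9
    sigma_e: float = 0.3
    pbf_base_bw: float = 0.35
    pbf_scale_bw: float = 0.125
    pbf_min_bw: float = 0.05
    # IMU corruption
    imu_wobble_deg: float = 2.0        # sagittal-axis RMS, low-frequency
    imu_wobble_offaxis_deg: float = 1.0
    imu_wobble_cutoff_hz: float = 3.0
    imu_white_deg: float = 0.3
    drift_rate_deg_s: float = 0.05     # sd of per-trial heading-drift rate
    mounting_misalign_deg: float = 5.0
    delay_range: tuple = (0.090, 0.180)
    # marker corruption
    marker_noise_m: float = 0.0005
    trochanter_offset_sd_m: float = 0.010

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name.endswith(("_sd", "_cv", "_deg", "_m", "_n")) and \
                    isinstance(v, float) and v < 0:
                raise ValueError(f"{f.name} must be >= 0")
        if any(sf <= 0 for sf in self.sf_levels):
            raise ValueError("sf_levels must be positive")

    def noiseless(self) -> "SimConfig":
        """Copy with every corruption source switched off."""
        return dataclasses.replace(
            self, participant_angle_sd=0.0, stride_angle_sd=0.0,
            stride_common_sd=0.0, stride_period_jitter_s=0.0,
            duty_participant_sd=0.0, duty_stride_sd=0.0,
            vertical_peak_cv=0.0, force_noise_n=0.0, sigma_b=0.0,
            sigma_e=0.0, imu_wobble_deg=0.0, imu_wobble_offaxis_deg=0.0,
            imu_white_deg=0.0, drift_rate_deg_s=0.0, marker_noise_m=0.0,
            trochanter_offset_sd_m=0.0, leg_length_sd=0.0, mass_sd=0.0,
            thigh_fraction_sd=0.0, og_speed_sd=0.0, og_sf_sd=0.0)

    @property
    def run_start(self) -> float:
        return self.stand_duration + self.maneuver_duration + self.lead_in

    def condition_labels(self):
        return [f"TM_SF{sf}" for sf in self.sf_levels] + ["OG"]


@dataclasses.dataclass
class TrialTruth:
    """Exact generative state of one simulated trial."""

    condition: str
    time: np.ndarray                 # 200 Hz lab-clock grid
    theta_true: dict                 # segment -> deg series on `time`
    fc_times: np.ndarray
    to_times: np.ndarray
    strides: pd.DataFrame            # per-stride generative table
    lag: float                       # IMU start delay (s)
    drift_rate: float                # deg/s about gravity
    coefficients: dict               # generative b, sigma_b, sigma_e


# ----------------------------------------------------------------------
# direct stride-level and LMM-level samplers (no waveforms)

def simulate_lmm_dataset(beta, sigma_b, sigma_e, n_groups, n_per_group,
                         rng, predictor_group_sd: float = 0.0
                         ) -> pd.DataFrame:
    """Sample directly from the standardized random-intercept model.

    y = X beta + alpha_i + eps with X ~ N(0, 1) (optionally with
    group-level predictor shifts), alpha_i ~ N(0, sigma_b^2),
    eps ~ N(0, sigma_e^2).  Used for estimator-recovery checks.
    """
    beta = np.asarray(beta, dtype=float)
    p = len(beta)
    rows = []
    for g in range(n_groups):
        shift = rng.normal(0.0, predictor_group_sd, size=p)
        X = rng.normal(0.0, 1.0, size=(n_per_group, p)) + shift
        alpha = rng.normal(0.0, sigma_b)
        y = X @ beta + alpha + rng.normal(0.0, sigma_e, size=n_per_group)
        df = pd.DataFrame(X, columns=[f"x{j+1}" for j in range(p)])
        df["y"] = y
        df["participant_id"] = f"P{g:02d}"
        rows.append(df)
    return pd.concat(rows, ignore_index=True)


def _draw_participant(config: SimConfig, index: int):
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1000 + index]))
    leg = max(0.6, rng.normal(config.leg_length_mean, config.leg_length_sd))
    mass = max(40.0, rng.normal(config.mass_mean, config.mass_sd))
    frac = np.clip(rng.normal(config.thigh_fraction_mean,
                              config.thigh_fraction_sd), 0.4, 0.6)
    anthro = ParticipantAnthro(
        participant_id=f"P{index:02d}", mass=mass, leg_length=leg,
        thigh_length=frac * leg, shank_length=(1 - frac) * leg,
        foot_length=config.foot_length)
    return {
        "anthro": anthro,
        "angle_offset": rng.normal(0.0, config.participant_angle_sd, size=3),
        "alpha_std": rng.normal(0.0, config.sigma_b),
        "duty_offset": rng.normal(0.0, config.duty_participant_sd),
        "og_speed": max(1.5, rng.normal(config.og_speed_mean,
                                        config.og_speed_sd)),
        "og_sf": float(np.clip(rng.normal(config.og_sf_mean, config.og_sf_sd),
                               70.0, 100.0)),
        "trochanter_dx": rng.normal(0.0, config.trochanter_offset_sd_m),
    }


def _mounting_rotations(config: SimConfig, index: int):
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 2000 + index]))
    out = {}
    for seg in ("thigh", "shank", "foot"):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.normal(0.0, config.mounting_misalign_deg))
        out[seg] = Rotation.from_rotvec(angle * axis)
    return out


def _angle_means(config: SimConfig, level: float):
    """FC-angle population means (deg) at fractional SF level 0..4."""
    return np.array([
        config.thigh_fc_base - config.thigh_fc_slope * level,
        config.shank_fc_base - config.shank_fc_slope * level,
        config.foot_fc_base - config.foot_fc_slope * level,
    ])


def _angle_pop_stats(config: SimConfig, condition_class: str):
    """Analytic pooled mean/sd of FC angles within a condition class.

    These constants define the z-scores entering the braking-force
    generative model, so the generative coefficients live on the same
    standardized scale the analysis uses.
    """
    slopes = np.array([config.thigh_fc_slope, config.shank_fc_slope,
                       config.foot_fc_slope])
    if condition_class == "TM":
        level_mean, level_var = 2.0, 2.0
    else:
        level_mean = (config.og_sf_mean - config.sf_levels[0]) / 5.0
        level_var = (config.og_sf_sd / 5.0) ** 2
    mu = _angle_means(config, level_mean)
    var = (slopes ** 2 * level_var + config.participant_angle_sd ** 2
           + config.stride_common_sd ** 2 + config.stride_angle_sd ** 2)
    return mu, np.sqrt(var)


def _snap(x: float, rate: float) -> float:
    return round(x * rate) / rate


def _stride_rows(config: SimConfig, part: dict, condition: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Per-stride generative truth for one trial."""
    anthro = part["anthro"]
    if condition.startswith("TM"):
        sf = float(condition.split("SF")[1])
        level = (sf - config.sf_levels[0]) / 5.0
        duration = config.tm_duration
        cond_class = "TM"
        speed = config.tm_speed
    else:
        sf = part["og_sf"]
        level = (sf - config.sf_levels[0]) / 5.0
        duration = config.og_duration
        cond_class = "OG"
        speed = part["og_speed"]
    mu_cond = _angle_means(config, level) + part["angle_offset"]
    mu_pop, sd_pop = _angle_pop_stats(config, cond_class)

    T_nom = 60.0 / sf
    rows = []
    t = 0.0
    k = 0
    while t + T_nom <= duration + 1e-9:
        T = _snap(T_nom + rng.normal(0.0, config.stride_period_jitter_s),
                  config.marker_rate)
        T = max(T, 0.4)
        common = rng.normal(0.0, config.stride_common_sd)
        theta = (mu_cond + common
                 + rng.normal(0.0, config.stride_angle_sd, size=3))
        z = (theta - mu_pop) / np.where(sd_pop > 0, sd_pop, 1.0)
        eps = rng.normal(0.0, config.sigma_e)
        pbf_std = (config.b_thigh * z[0] + config.b_shank * z[1]
                   + config.b_foot * z[2] + part["alpha_std"] + eps)
        pbf_bw = max(config.pbf_min_bw,
                     config.pbf_base_bw + config.pbf_scale_bw * pbf_std)
        duty = float(np.clip(
            config.duty_base + config.duty_slope * level
            + part["duty_offset"]
            + rng.normal(0.0, config.duty_stride_sd), 0.15, 0.5))
        os_raw = (anthro.thigh_length * np.sin(np.radians(theta[0]))
                  + anthro.shank_length * np.sin(np.radians(theta[1])))
        v_k = speed * (1.0 + rng.normal(0.0, 0.015)) if cond_class == "OG" \
            else speed
        rows.append({
            "participant_id": anthro.participant_id, "condition": condition,
            "stride_index": k, "period_s": T,
            "theta_thigh_fc": theta[0], "theta_shank_fc": theta[1],
            "theta_foot_fc": theta[2],
            "overstriding_m": os_raw,
            "overstriding_norm": os_raw / anthro.leg_length,
            "pbf_bw": pbf_bw, "stride_frequency": 60.0 / T,
            "duty_cycle": duty, "speed": v_k,
        })
        t += T
        k += 1
    return pd.DataFrame(rows)


def simulate_stride_table(config: SimConfig) -> pd.DataFrame:
    """Per-stride generative truth for the whole study (no waveforms).

    The fast path for statistical-recovery experiments; the waveform
    generator anchors its trials to exactly these per-stride values.
    """
    frames = []
    for i in range(config.n_participants):
        part = _draw_participant(config, i)
        for ci, cond in enumerate(config.condition_labels()):
            rng = np.random.default_rng(np.random.SeedSequence(
                [int(config.seed), 3000 + i, ci]))
            frames.append(_stride_rows(config, part, cond, rng))
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# waveform synthesis

_SEGS = ("thigh", "shank", "foot")

# canonical within-stride angle waveforms (deg), phase 0 = foot contact;
# two to three harmonics of the stride, loosely shaped on running kinematics
_SHAPES = {
    "thigh": lambda ph: (18 * np.cos(2 * np.pi * ph)
                         + 6 * np.sin(2 * np.pi * ph)
                         - 3 * np.cos(4 * np.pi * ph)),
    "shank": lambda ph: (10 * np.cos(2 * np.pi * ph)
                         - 22 * np.sin(2 * np.pi * ph)
                         - 6 * np.cos(4 * np.pi * ph)
                         + 4 * np.sin(4 * np.pi * ph)),
    "foot": lambda ph: (12 * np.cos(2 * np.pi * ph)
                        - 26 * np.sin(2 * np.pi * ph)
                        + 5 * np.sin(4 * np.pi * ph)
                        - 4 * np.cos(4 * np.pi * ph)),
}

_MANEUVER = {  # (step amplitude, swing amplitude) deg
    "thigh": (10.0, 30.0),
    "shank": (25.0, 35.0),
    "foot": (20.0, 25.0),
}


def _maneuver_angle(t: np.ndarray, seg: str, t0: float) -> np.ndarray:
    """Calibration maneuver: hard step then forward/backward leg swing.

    The step is fast (~0.3 s) so its edges carry high-frequency content
    that pins the cross-correlation peak for synchronization.
    """
    a_step, a_swing = _MANEUVER[seg]
    out = np.zeros_like(t)
    u = (t - (t0 + 0.3)) / 0.3
    m = (u >= 0) & (u <= 1)
    out[m] += a_step * np.sin(np.pi * u[m]) ** 2
    v = (t - (t0 + 0.9)) / 1.9
    m = (v >= 0) & (v <= 1)
    out[m] += (a_swing * np.sin(2 * np.pi * 2.0 * 1.9 * v[m])
               * np.sin(np.pi * v[m]) ** 2)
    return out


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


def _continuous_angles(config: SimConfig, strides: pd.DataFrame,
                       time: np.ndarray) -> dict:
    """Build per-frame true angles through the stride FC targets.

    Within stride k the angle is the canonical shape plus an offset blended
    linearly from this stride's FC target to the next, so theta(FC_k)
    equals the target exactly and the series is continuous.
    """
    t_run = config.run_start
    periods = strides["period_s"].to_numpy()
    fc = t_run + np.concatenate([[0.0], np.cumsum(periods)])
    targets = {
        "thigh": strides["theta_thigh_fc"].to_numpy(),
        "shank": strides["theta_shank_fc"].to_numpy(),
        "foot": strides["theta_foot_fc"].to_numpy(),
    }
    out = {}
    t_stand_end = config.stand_duration
    blend_start = t_stand_end + config.maneuver_duration
    for seg in _SEGS:
        tg = targets[seg]
        tg_ext = np.concatenate([tg, [tg[-1]]])  # target at final FC
        theta = np.zeros_like(time)
        # maneuver
        man = (time >= t_stand_end) & (time < blend_start)
        theta[man] = _maneuver_angle(time[man], seg, t_stand_end)
        # blend-in and running
        run = time >= blend_start
        tt = time[run]
        k = np.clip(np.searchsorted(fc, tt, side="right") - 1, 0,
                    len(periods) - 1)
        ph = (tt - fc[k]) / periods[k]
        shape0 = _SHAPES[seg](np.zeros(1))[0]
        off = np.where(
            ph < 0, tg_ext[0],
            (1 - np.clip(ph, 0, 1)) * tg_ext[k]
            + np.clip(ph, 0, 1) * tg_ext[np.minimum(k + 1, len(tg))])
        th_run = _SHAPES[seg](ph) - shape0 + off
        w = _smoothstep((tt - blend_start) / (t_run - blend_start - 0.2))
        theta[run] = w * th_run
        out[seg] = theta
    return out, fc


def _rot2d(theta_deg: np.ndarray, vx: float, vz: float):
    th = np.radians(theta_deg)
    return (vx * np.cos(th) - vz * np.sin(th),
            vx * np.sin(th) + vz * np.cos(th))


def _markers_from_angles(config: SimConfig, part: dict, condition: str,
                         time: np.ndarray, theta: dict, fc: np.ndarray,
                         strides: pd.DataFrame,
                         rng: np.random.Generator) -> pd.DataFrame:
    anthro = part["anthro"]
    Lt, Ls, Lf = (anthro.thigh_length, anthro.shank_length,
                  anthro.foot_length)
    h_hip = anthro.leg_length + 0.10
    th_t, th_s, th_f = theta["thigh"], theta["shank"], theta["foot"]

    # hip trajectory
    if condition == "OG" and len(strides):
        v = strides["speed"].to_numpy()
        periods = strides["period_s"].to_numpy()
        x_at_fc = np.concatenate([[0.0], np.cumsum(v * periods)])
        hip_x = np.zeros_like(time)
        run = time >= config.run_start
        tt = time[run]
        k = np.clip(np.searchsorted(fc, tt, side="right") - 1, 0,
                    len(periods) - 1)
        hip_x[run] = x_at_fc[k] + v[k] * np.clip(tt - fc[k], 0, None)
        hip_x[run] = np.where(tt < fc[0], 0.0, hip_x[run])
    else:
        hip_x = np.zeros_like(time)
    # gentle within-stride oscillation and vertical bounce during running
    if len(strides):
        periods = strides["period_s"].to_numpy()
        run = time >= fc[0]
        tt = time[run]
        k = np.clip(np.searchsorted(fc, tt, side="right") - 1, 0,
                    len(periods) - 1)
        ph = np.clip((tt - fc[k]) / periods[k], 0, 1)
        osc_x = np.zeros_like(time)
        osc_z = np.zeros_like(time)
        osc_x[run] = 0.02 * np.sin(2 * np.pi * ph)
        osc_z[run] = -0.03 * np.sin(np.pi * ph) ** 2
    else:
        osc_x = osc_z = np.zeros_like(time)
    hip = np.stack([hip_x + osc_x, np.zeros_like(time),
                    h_hip + osc_z], axis=1)

    knee = hip + np.stack(
        [Lt * np.sin(np.radians(th_t)), np.zeros_like(time),
         -Lt * np.cos(np.radians(th_t))], axis=1)
    ankle = knee + np.stack(
        [Ls * np.sin(np.radians(th_s)), np.zeros_like(time),
         -Ls * np.cos(np.radians(th_s))], axis=1)
    hx, hz = _rot2d(th_f, -0.06, -0.05)
    heel = ankle + np.stack([hx, np.zeros_like(time), hz], axis=1)
    tx, tz = _rot2d(th_f, Lf, 0.0)
    toe = heel + np.stack([tx, np.zeros_like(time), tz], axis=1)

    cols = {}

    def put(name, pts, dy=0.0):
        noisy = pts + rng.normal(0.0, config.marker_noise_m,
                                 size=pts.shape) \
            if config.marker_noise_m > 0 else pts
        cols[f"{name}_x"] = noisy[:, 0]
        cols[f"{name}_y"] = noisy[:, 1] + dy
        cols[f"{name}_z"] = noisy[:, 2]

    troch = hip.copy()
    troch[:, 0] += part["trochanter_dx"]
    put("trochanter", troch, dy=0.08)
    put("lat_epicondyle", knee, dy=0.05)
    put("med_epicondyle", knee, dy=-0.05)
    put("lat_malleolus", ankle, dy=0.04)
    put("med_malleolus", ankle, dy=-0.04)
    put("calcaneus", heel, dy=0.0)
    put("metatarsal_2", toe, dy=0.0)
    supra = hip + np.array([0.02, 0.0, 0.60])
    put("suprasternal", supra, dy=0.0)
    return pd.DataFrame(cols)


def simulate_grf(config: SimConfig, part: dict, time_f: np.ndarray,
                 fc: np.ndarray, strides: pd.DataFrame,
                 rng: np.random.Generator):
    """Force-plate channels at the force rate.

    The vertical channel crosses the 20 N threshold exactly at the true
    FC and TO instants (smooth sine-squared stance bumps on a widened
    support); the anterior-posterior channel's braking lobe peaks exactly
    at each stride's generative braking force.
    """
    bw = part["anthro"].body_weight
    thr = config.fc_threshold_n
    fz = np.zeros_like(time_f)
    fx = np.zeros_like(time_f)
    t_run = config.run_start

    # standing and maneuver: weight on the plate, no threshold crossings
    stand = time_f < t_run - 0.2
    fz[stand] = bw
    man = (time_f >= config.stand_duration) & \
          (time_f < config.stand_duration + 1.0)
    fz[man] += 0.25 * bw * np.sin(
        np.pi * (time_f[man] - config.stand_duration)) ** 2
    # smooth drop into flight before the first contact
    drop = (time_f >= t_run - 0.2) & (time_f < t_run - 0.08)
    u = (time_f[drop] - (t_run - 0.2)) / 0.12
    fz[drop] = bw * 0.5 * (1 + np.cos(np.pi * u))

    to_times = []
    # one stance per stride plus a final stance at the closing FC so the
    # last stride interval is bounded by detectable contacts
    for k in range(len(strides) + 1):
        row = strides.iloc[min(k, len(strides) - 1)]
        T, duty = row["period_s"], row["duty_cycle"]
        fc_k = fc[k]
        Tc = duty * T
        if k < len(strides):
            to_times.append(fc_k + Tc)
        A = config.vertical_peak_bw * bw * (
            1.0 + rng.normal(0.0, config.vertical_peak_cv))
        A = max(A, 8 * thr)
        c = np.arcsin(np.sqrt(thr / A)) / np.pi
        d = Tc * c / (1 - 2 * c)
        lo, hi = fc_k - d, fc_k + Tc + d
        m = (time_f >= lo) & (time_f <= hi)
        u = (time_f[m] - lo) / (hi - lo)
        fz[m] = A * np.sin(np.pi * u) ** 2
        # anterior-posterior: braking lobe then propulsive lobe
        pbf_n = row["pbf_bw"] * bw
        tb = 0.42 * Tc
        mb = (time_f >= fc_k) & (time_f <= fc_k + tb)
        v = (time_f[mb] - fc_k) / tb
        fx[mb] = -pbf_n * np.sin(np.pi * v) ** 2
        mp = (time_f > fc_k + tb) & (time_f <= fc_k + Tc)
        w = (time_f[mp] - (fc_k + tb)) / (Tc - tb)
        fx[mp] = 0.9 * pbf_n * np.sin(np.pi * w) ** 2
    if config.force_noise_n > 0:
        fz = fz + rng.normal(0.0, config.force_noise_n, size=fz.shape)
        fx = fx + rng.normal(0.0, config.force_noise_n, size=fx.shape)
    data = pd.DataFrame({"f_x": fx, "f_y": np.zeros_like(fx), "f_z": fz})
    return data, np.asarray(to_times)


def _lowpass_noise(rng, n, rate, cutoff, rms):
    if rms == 0 or n < 50:
        return np.zeros(n)
    x = rng.normal(0.0, 1.0, size=n)
    sos = scipy.signal.butter(2, cutoff, btype="low", fs=rate, output="sos")
    y = scipy.signal.sosfiltfilt(sos, x)
    s = y.std()
    return y / s * rms if s > 0 else np.zeros(n)


def simulate_imu(config: SimConfig, time_m: np.ndarray, theta: dict,
                 mounts: dict, lag: float, drift_rate: float,
                 rng: np.random.Generator) -> dict:
    """IMU orientation streams for the three segments.

    Measured orientation = drift about gravity (accumulating after the
    standing window) composed with the true planar segment rotation, a
    soft-tissue wobble, and the constant mounting misalignment; sampled at
    the IMU rate on a clock that starts ``lag`` seconds after the lab
    clock.
    """
    t_end = time_m[-1]
    n = int(np.floor((t_end - lag) * config.imu_rate)) + 1
    t_lab = lag + np.arange(n) / config.imu_rate
    out = {}
    for seg in _SEGS:
        th = np.interp(t_lab, time_m, theta[seg])
        psi = np.radians(drift_rate) * np.maximum(
            0.0, t_lab - config.stand_duration)
        rot = (Rotation.from_euler("z", psi[:, None])
               * Rotation.from_euler("y", -np.radians(th)[:, None]))
        wob = np.zeros((n, 3))
        for ax, rms in ((0, config.imu_wobble_offaxis_deg),
                        (1, config.imu_wobble_deg),
                        (2, config.imu_wobble_offaxis_deg)):
            wob[:, ax] = _lowpass_noise(rng, n, config.imu_rate,
                                        config.imu_wobble_cutoff_hz, rms)
        if config.imu_white_deg > 0:
            wob += rng.normal(0.0, config.imu_white_deg, size=(n, 3))
        rot_clean = rot * mounts[seg]
        if np.any(wob):
            rot = rot * Rotation.from_rotvec(np.radians(wob))
        rot = rot * mounts[seg]
        q_xyzw = rot.as_quat()
        quat = np.column_stack([q_xyzw[:, 3], q_xyzw[:, 0],
                                q_xyzw[:, 1], q_xyzw[:, 2]])
        # gyroscope: true angular rate in the sensor frame (finite
        # differences of the noise-free motion) plus white rate noise
        rel = rot_clean[:-1].inv() * rot_clean[1:]
        gyro = np.vstack([rel.as_rotvec(), rel.as_rotvec()[-1:]]) \
            * config.imu_rate
        gyro = np.degrees(gyro)
        if config.imu_white_deg > 0:
            gyro = gyro + rng.normal(0.0, 0.5, size=gyro.shape)
        out[seg] = OrientationSeries(quat=quat, sample_rate=config.imu_rate,
                                     t0=0.0, segment=seg, gyro=gyro)
    return out


def simulate_participant(config: SimConfig, index: int):
    """All trials for one participant, with full ground truth.

    Returns ``(anthro, trials)`` where ``trials`` maps condition label to
    a dict with keys ``markers``/``forces`` (TrialTable), ``imu`` (segment
    -> OrientationSeries) and ``truth`` (TrialTruth); plus a ``static``
    trial with markers only.
    """
    part = _draw_participant(config, index)
    mounts = _mounting_rotations(config, index)
    anthro = part["anthro"]
    trials = {}
    for ci, cond in enumerate(config.condition_labels()):
        rng = np.random.default_rng(np.random.SeedSequence(
            [int(config.seed), 3000 + index, ci]))
        strides = _stride_rows(config, part, cond, rng)
        rng2 = np.random.default_rng(np.random.SeedSequence(
            [int(config.seed), 4000 + index, ci]))
        duration = (config.run_start
                    + float(strides["period_s"].sum()) + 0.4)
        n_m = int(round(duration * config.marker_rate)) + 1
        time_m = np.arange(n_m) / config.marker_rate
        theta, fc_all = _continuous_angles(config, strides, time_m)
        fc = fc_all  # includes final FC (len = n_strides + 1)
        markers = _markers_from_angles(config, part, cond, time_m, theta,
                                       fc, strides, rng2)
        n_f = int(round(duration * config.force_rate)) + 1
        time_f = np.arange(n_f) / config.force_rate
        force_data, to_times = simulate_grf(config, part, time_f, fc,
                                            strides, rng2)
        lag = float(rng2.uniform(*config.delay_range))
        drift_rate = float(rng2.normal(0.0, config.drift_rate_deg_s))
        imu = simulate_imu(config, time_m, theta, mounts, lag, drift_rate,
                           rng2)
        truth = TrialTruth(
            condition=cond, time=time_m, theta_true=theta,
            fc_times=fc, to_times=to_times, strides=strides, lag=lag,
            drift_rate=drift_rate,
            coefficients={"b_thigh": config.b_thigh,
                          "b_shank": config.b_shank,
                          "b_foot": config.b_foot,
                          "sigma_b": config.sigma_b,
                          "sigma_e": config.sigma_e,
                          "alpha_std": part["alpha_std"]})
        trials[cond] = {
            "markers": TrialTable(data=markers,
                                  sample_rate=config.marker_rate,
                                  kind="markers"),
            "forces": TrialTable(data=force_data,
                                 sample_rate=config.force_rate,
                                 kind="forces"),
            "imu": imu,
            "truth": truth,
        }
    # static standing trial (markers only, 1 s)
    rng3 = np.random.default_rng(np.random.SeedSequence(
        [int(config.seed), 5000 + index]))
    n_s = int(round(1.0 * config.marker_rate)) + 1
    time_s = np.arange(n_s) / config.marker_rate
    zeros = {seg: np.zeros_like(time_s) for seg in _SEGS}
    static = _markers_from_angles(config, part, "static", time_s, zeros,
                                  np.array([np.inf]), pd.DataFrame(), rng3)
    trials["static"] = {
        "markers": TrialTable(data=static, sample_rate=config.marker_rate,
                              kind="markers")}
    return anthro, trials


def simulate_study(config: SimConfig):
    """Simulate every participant.  Returns list of (anthro, trials)."""
    return [simulate_participant(config, i)
            for i in range(config.n_participants)]


def write_study(config: SimConfig, outdir: str | Path) -> None:
    """Write the study to disk in the pipeline's CSV layout."""
    from .dataio import write_trial

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for i in range(config.n_participants):
        anthro, trials = simulate_participant(config, i)
        pdir = outdir / anthro.participant_id
        pdir.mkdir(exist_ok=True)
        meta.append(dataclasses.asdict(anthro))
        for cond, trial in trials.items():
            tdir = pdir / cond
            tdir.mkdir(exist_ok=True)
            write_trial(trial["markers"], tdir / "markers.csv")
            if "forces" in trial:
                write_trial(trial["forces"], tdir / "forces.csv")
            if "imu" in trial:
                for seg, series in trial["imu"].items():
                    df = pd.DataFrame(
                        series.quat, columns=["q_w", "q_x", "q_y", "q_z"])
                    for j, ax in enumerate("xyz"):
                        df[f"gyro_{ax}"] = series.gyro[:, j]
                    acc = series.rotations().inv().apply([0, 0, GRAV])
                    for j, ax in enumerate("xyz"):
                        df[f"acc_{ax}"] = acc[:, j]
                    df.insert(0, "time_s", series.time)
                    df.to_csv(tdir / f"imu_{seg}.csv", index=False,
                              float_format="%.10g")
            if "truth" in trial:
                tr = trial["truth"]
                tr.strides.to_csv(tdir / "truth_strides.csv", index=False)
                with open(tdir / "truth.json", "w") as fh:
                    json.dump({"lag": tr.lag, "drift_rate": tr.drift_rate,
                               "fc_times": tr.fc_times.tolist(),
                               "to_times": tr.to_times.tolist(),
                               "coefficients": tr.coefficients}, fh,
                              indent=1)
    with open(outdir / "participants.json", "w") as fh:
        json.dump(meta, fh, indent=1)
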