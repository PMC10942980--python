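"""Validation experiments: quantitative checks of every pipeline stage.

Each function runs one self-contained experiment against the synthetic
generator's ground truth and returns a dict of measured quantities.  They
are consumed by the acceptance script and by the test suite; all
randomness is controlled through the ``seed`` argument.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import imu as imu_mod
from .dataio import PipelineConfig
from .gait import detect_foot_contacts, peak_braking_force
from .kinematics import marker_xyz, overstriding_from_markers
from .mixedlm import RandomInterceptModel
from .pipeline import process_trial, run_all
from .signal import filter_table
from .simulate import (SimConfig, _mounting_rotations, simulate_imu,
                       simulate_lmm_dataset, simulate_participant)

__all__ = [
    "geometric_identity_check",
    "drift_annihilation_check",
    "lag_recovery_check",
    "event_detection_check",
    "lmm_fixture_check",
    "parameter_recovery_check",
    "full_study_check",
    "em_reml_random_intercept",
]


def geometric_identity_check(seed: int = 0) -> dict:
    """Marker overstriding vs L_t sin(theta_t) + L_s sin(theta_s), noiseless."""
    cfg = SimConfig(n_participants=1, tm_duration=6, og_duration=6,
                    seed=seed).noiseless()
    anthro, trials = simulate_participant(cfg, 0)
    worst, n = 0.0, 0
    for cond, tr in trials.items():
        if cond == "static":
            continue
        st = tr["truth"].strides
        m = tr["markers"]
        troch = marker_xyz(m, "trochanter")
        mall = marker_xyz(m, "lat_malleolus")
        for k in range(len(st)):
            v = overstriding_from_markers(troch, mall, m.time,
                                          tr["truth"].fc_times[k],
                                          anthro.leg_length)
            expect = (anthro.thigh_length
                      * np.sin(np.radians(st.theta_thigh_fc[k]))
                      + anthro.shank_length
                      * np.sin(np.radians(st.theta_shank_fc[k])))
            worst = max(worst, abs(v.raw - expect))
            n += 1
    return {"max_error_m": worst, "n_strides": n}


def drift_annihilation_check(seed: int = 0, total_drift_deg: float = 30.0
                             ) -> dict:
    """Per-frame vs static-pose angle error under pure heading drift."""
    cfg = SimConfig(n_participants=1, tm_duration=25, og_duration=6,
                    seed=seed).noiseless()
    _, trials = simulate_participant(cfg, 0)
    tr = trials["TM_SF80"]
    truth = tr["truth"]
    rate = total_drift_deg / (truth.time[-1] - cfg.stand_duration)
    rng = np.random.default_rng(seed)
    mounts = _mounting_rotations(cfg, 0)
    imu = simulate_imu(cfg, truth.time, truth.theta_true, mounts,
                       lag=0.12, drift_rate=rate, rng=rng)
    s = imu["shank"]
    mounting = imu_mod.static_pose_calibrate(s, (0.2, 1.4))
    pf = imu_mod.sagittal_angle_per_frame_method(s, mounting)
    stat = imu_mod.sagittal_angle_static_method(s, mounting)
    true_at = np.interp(0.12 + s.time, truth.time,
                        truth.theta_true["shank"])
    return {
        "per_frame_max_error_deg": float(np.max(np.abs(pf.theta - true_at))),
        "static_max_error_deg": float(np.max(np.abs(stat.theta - true_at))),
        "total_drift_deg": total_drift_deg,
        "n_frames": len(s),
    }


def lag_recovery_check(seed: int = 0, n_replicates: int = 100) -> dict:
    """Recovery of injected 90-180 ms IMU start delays, default noise."""
    pcfg = PipelineConfig()
    errors = []
    n_participants = int(np.ceil(n_replicates / 6))
    cfg = SimConfig(n_participants=n_participants, tm_duration=5,
                    og_duration=5, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n_participants):
            anthro, trials = simulate_participant(cfg, i)
            for cond, tr in trials.items():
                if cond == "static" or len(errors) >= n_replicates:
                    continue
                df = process_trial(tr, anthro.participant_id, cond,
                                   anthro.leg_length, pcfg)
                errors.append(df.attrs["lag"] - tr["truth"].lag)
    errors = np.asarray(errors)
    sample = 1.0 / pcfg.analysis_rate_hz
    return {
        "n_within_one_sample": int(np.sum(np.abs(errors) <= sample)),
        "n_replicates": len(errors),
        "max_abs_error_ms": float(np.max(np.abs(errors)) * 1000),
        "rms_error_ms": float(np.std(errors) * 1000),
    }


def event_detection_check(seed: int = 0, n_participants: int = 2) -> dict:
    """FC/TO timing and braking-peak recovery on synthetic force traces."""
    cfg = SimConfig(n_participants=n_participants, tm_duration=10,
                    og_duration=10, seed=seed)
    fc_err, to_err, pbf_err = [], [], []
    for i in range(n_participants):
        anthro, trials = simulate_participant(cfg, i)
        for cond, tr in trials.items():
            if cond == "static":
                continue
            truth = tr["truth"]
            forces = filter_table(tr["forces"], 50.0)
            ev = detect_foot_contacts(forces.channel("f_z"),
                                      forces.sample_rate)
            n = len(truth.strides)
            fc_err.extend(np.abs(ev.fc_times[:n + 1] - truth.fc_times))
            for k, (fc0, to, _) in enumerate(ev.stride_bounds()):
                to_err.append(abs(to - truth.to_times[k]))
                p = peak_braking_force(forces.channel("f_x"), forces.time,
                                       (fc0, to), anthro.body_weight)
                pbf_err.append(abs(p - truth.strides.pbf_bw[k])
                               / truth.strides.pbf_bw[k])
    return {
        "fc_max_error_ms": float(np.max(fc_err) * 1000),
        "to_max_error_ms": float(np.max(to_err) * 1000),
        "pbf_max_rel_error_pct": float(np.max(pbf_err) * 100),
        "n_strides": len(pbf_err),
    }


# printed 3-group fixture for the estimator cross-check
LMM_FIXTURE = pd.DataFrame({
    "participant_id": ["A"] * 4 + ["B"] * 4 + ["C"] * 4,
    "x": [-1.0, 0.0, 1.0, 2.0, -2.0, -1.0, 0.0, 1.0, 0.0, 1.0, 2.0, 3.0],
    "y": [0.9, 2.1, 2.9, 4.2, -0.5, 0.6, 1.4, 2.6, 2.2, 3.1, 4.0, 5.3],
})


def em_reml_random_intercept(y, X, groups, n_iter=200_000, tol=1e-14):
    """EM algorithm for REML in a random-intercept model.

    An independent cross-check of the package's profiled one-dimensional
    REML: Laird-Ware EM with the REML correction for fixed-effect
    uncertainty, sharing no code with :mod:`overstride.mixedlm`.
    Returns ``(beta, sigma2_b, sigma2_e)``.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    labels = np.unique(groups)
    idx = [np.nonzero(np.asarray(groups) == g)[0] for g in labels]
    m, (n, p) = len(labels), X.shape
    s2b = s2e = float(np.var(y)) / 2 + 1e-3
    for _ in range(n_iter):
        XtWX = np.zeros((p, p))
        XtWy = np.zeros(p)
        ws = []
        for ix in idx:
            ni = len(ix)
            w = s2b / (s2e * (s2e + s2b * ni))
            Xi, yi = X[ix], y[ix]
            WX = Xi / s2e - w * np.outer(np.ones(ni), Xi.sum(0))
            XtWX += Xi.T @ WX
            XtWy += WX.T @ yi
            ws.append(w)
        C = np.linalg.inv(XtWX)
        beta = C @ XtWy
        nb = ne = 0.0
        for ix, w in zip(idx, ws):
            ni = len(ix)
            Xi, yi = X[ix], y[ix]
            ri = yi - Xi @ beta
            one_W_r = ri.sum() / s2e - w * ni * ri.sum()
            bi = s2b * one_W_r
            one_W_one = ni / s2e - w * ni * ni
            one_W_X = Xi.sum(0) / s2e - w * ni * Xi.sum(0)
            vi = s2b - s2b ** 2 * one_W_one + s2b ** 2 * one_W_X @ C @ one_W_X
            nb += bi ** 2 + vi
            eps = ri - bi
            Wi = np.eye(ni) / s2e - w * np.ones((ni, ni))
            WXi = Wi @ Xi
            tr_cond = (s2e * ni - s2e ** 2 * np.trace(Wi)
                       + s2e ** 2 * np.trace(WXi @ C @ WXi.T))
            ne += eps @ eps + tr_cond
        nb, ne = nb / m, ne / n
        if abs(nb - s2b) < tol and abs(ne - s2e) < tol:
            s2b, s2e = nb, ne
            break
        s2b, s2e = nb, ne
    return beta, s2b, s2e


def lmm_fixture_check() -> dict:
    """Profiled REML vs EM oracle; single-group collapse to OLS."""
    fx = LMM_FIXTURE
    fit = RandomInterceptModel.from_dataframe(fx, "y", ["x"]).fit()
    X = np.column_stack([np.ones(len(fx)), fx["x"]])
    beta, s2b, s2e = em_reml_random_intercept(
        fx["y"].to_numpy(), X, fx["participant_id"].to_numpy())
    em_diff = max(float(np.max(np.abs(fit.params.to_numpy() - beta))),
                  abs(fit.sigma2_b - s2b), abs(fit.sigma2_e - s2e))
    # single group: REML must reduce to ordinary least squares
    rng = np.random.default_rng(17)
    x = rng.normal(size=(40, 2))
    y = 1.5 + x @ np.array([0.4, -0.7]) + rng.normal(0, 0.5, 40)
    df = pd.DataFrame({"x1": x[:, 0], "x2": x[:, 1], "y": y,
                       "participant_id": "only"})
    fit1 = RandomInterceptModel.from_dataframe(df, "y", ["x1", "x2"]).fit()
    Xd = np.column_stack([np.ones(40), x])
    beta_ols = np.linalg.lstsq(Xd, y, rcond=None)[0]
    ols_diff = float(np.max(np.abs(fit1.params.to_numpy() - beta_ols)))
    return {"em_oracle_max_abs_diff": em_diff,
            "single_group_ols_max_abs_diff": ols_diff,
            "n_obs_fixture": len(fx)}


def parameter_recovery_check(seed: int = 0, n_replicates: int = 100,
                             n_groups: int = 10, n_per_group: int = 75
                             ) -> dict:
    """Coefficient, coverage, ICC and R-squared recovery at study scale."""
    beta = np.array([0.6, 0.6, 0.05])
    sigma_b, sigma_e = 1.0, 0.3
    s2f = float(beta @ beta)           # X iid standard normal
    tot = s2f + sigma_b ** 2 + sigma_e ** 2
    icc_true = sigma_b ** 2 / (sigma_b ** 2 + sigma_e ** 2)
    r2m_true, r2c_true = s2f / tot, (s2f + sigma_b ** 2) / tot
    rng = np.random.default_rng(seed)
    errs, cover, iccs = [], [], []
    comps = np.zeros(3)  # mean of (s2f, s2b, s2e) across replicates
    for _ in range(n_replicates):
        df = simulate_lmm_dataset(beta, sigma_b, sigma_e, n_groups,
                                  n_per_group, rng)
        fit = RandomInterceptModel.from_dataframe(
            df, "y", ["x1", "x2", "x3"]).fit()
        est = fit.params[["x1", "x2", "x3"]].to_numpy()
        errs.append(np.abs(est - beta))
        ci = fit.conf_int().loc[["x1", "x2", "x3"]]
        cover.extend((ci["lower"].to_numpy() <= beta)
                     & (beta <= ci["upper"].to_numpy()))
        iccs.append(fit.icc)
        comps += np.array([fit.sigma2_f, fit.sigma2_b, fit.sigma2_e])
    comps /= n_replicates
    # R-squared checked on mean variance components: the per-replicate
    # ratio carries an O(1/n_groups) Jensen bias that is a property of
    # the 10-group design, not of the formulas under test
    r2m_hat = comps[0] / comps.sum()
    r2c_hat = (comps[0] + comps[1]) / comps.sum()
    return {
        "beta_mean_abs_error": float(np.mean(errs)),
        "ci95_coverage_pct": float(100 * np.mean(cover)),
        "icc_mean_abs_error": float(np.mean(np.abs(np.array(iccs)
                                                   - icc_true))),
        "r2_marginal_abs_error": float(abs(r2m_hat - r2m_true)),
        "r2_conditional_abs_error": float(abs(r2c_hat - r2c_true)),
        "n_replicates": n_replicates,
        "n_per_replicate": n_groups * n_per_group,
    }


def full_study_check(seed: int = 0, config: SimConfig | None = None) -> dict:
    """Default-configuration end-to-end run: structure + RMSE band."""
    cfg = config or SimConfig(seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_all(cfg)
    t = res["stride_records"]
    tm = t[t.condition.str.startswith("TM")]
    means = tm.groupby("condition")[["overstriding_m", "pbf_bw"]].mean() \
        .sort_index()
    g = tm.groupby(["participant_id", "condition"])[
        ["overstriding_m", "pbf_bw"]].mean().reset_index()
    os_range = g.groupby("participant_id")["overstriding_m"].agg(
        lambda x: x.max() - x.min())
    pbf_range = g.groupby("participant_id")["pbf_bw"].agg(
        lambda x: x.max() - x.min())
    fits = res["fits"]
    out = {
        "os_monotonic_decreasing": float(
            means["overstriding_m"].is_monotonic_decreasing),
        "pbf_monotonic_decreasing": float(
            means["pbf_bw"].is_monotonic_decreasing),
        "os_mean_range_cm": float(os_range.mean() * 100),
        "pbf_mean_range_bw": float(pbf_range.mean()),
        "r2m_mocap_minus_imu_os_tm": float(fits["1A"].r2_marginal
                                           - fits["1B"].r2_marginal),
        "r2m_mocap_minus_imu_os_og": float(fits["2A"].r2_marginal
                                           - fits["2B"].r2_marginal),
        "foot_coef_os_tm_mocap": float(
            fits["1A"].params["theta_foot_fc"]),
        "icc_pbf_tm_mocap": float(fits["3A"].icc),
        "icc_generative": cfg.sigma_b ** 2 / (cfg.sigma_b ** 2
                                              + cfg.sigma_e ** 2),
        "n_strides": len(t),
    }
    for cond in ("TM", "OG"):
        for seg in ("thigh", "shank", "foot"):
            out[f"rmse_fc_{cond.lower()}_{seg}_deg"] = float(
                res["rmse"][cond][seg])
    out["_fits"] = fits          # for callers wanting the full menu
    out["_records"] = t
    return out
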