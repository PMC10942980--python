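"""Random-intercept linear mixed models for repeated-measures stride data.

The analysis regresses a per-stride outcome (overstriding or peak braking
force) on sagittal segment angles at foot contact, with a participant-level
random intercept absorbing between-runner differences:

    y_ij = x_ij' beta + alpha_i + eps_ij,
    alpha_i ~ N(0, sigma2_b),  eps_ij ~ N(0, sigma2_e),

for stride j of participant i.  All model inputs are standardized as
z-scores (pooled within condition) so coefficients are unitless.

Estimation is restricted maximum likelihood (REML), profiled to a
one-dimensional deterministic optimization over the variance ratio
``lambda = sigma2_b / sigma2_e``: given lambda, the GLS coefficients and
the residual variance have closed forms because the marginal covariance is
block diagonal with compound-symmetric blocks.  Boundary fits
(sigma2_b = 0) collapse exactly to ordinary least squares, as does any
single-group dataset.

Reported per fit: standardized coefficients with Wald 95% CIs and normal
p-values, variance components, ICC = sigma2_b / (sigma2_b + sigma2_e),
participant intercepts (BLUPs), and marginal / conditional R-squared in
the Nakagawa-Schielzeth variance-ratio form.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

__all__ = [
    "zscore",
    "RandomInterceptModel",
    "RandomInterceptResults",
    "variance_explained",
    "rmse_fc",
    "run_model_menu",
    "render_model_table",
    "MODEL_MENU",
]


def zscore(table: pd.DataFrame, columns=None):
    """Standardize columns to zero mean, unit sd (ddof=1).

    Returns ``(standardized_table, params)`` where ``params`` maps column
    name to ``(mean, sd)`` for back-conversion.  Raises on zero-variance
    columns (naming them).
    """
    out = table.copy()
    params = {}
    for c in (columns if columns is not None else table.columns):
        x = table[c].to_numpy(dtype=float)
        mu, sd = float(np.mean(x)), float(np.std(x, ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"zero-variance column: {c}")
        out[c] = (x - mu) / sd
        params[c] = (mu, sd)
    return out, params


def zscore_inverse(table: pd.DataFrame, params) -> pd.DataFrame:
    """Undo :func:`zscore` using its returned parameters."""
    out = table.copy()
    for c, (mu, sd) in params.items():
        out[c] = out[c] * sd + mu
    return out


class RandomInterceptModel:
    """Linear mixed model with one random intercept per group.

    Parameters
    ----------
    endog : array (n,)
        Response variable.
    exog : array (n, k)
        Fixed-effect regressors (a constant column is added unless
        ``add_intercept=False``).
    groups : array (n,)
        Group labels (participant identifiers).
    exog_names : list of str, optional
    """

    def __init__(self, endog, exog, groups, exog_names=None,
                 add_intercept=True):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if len(y) != len(X):
            raise ValueError("endog and exog lengths differ")
        names = list(exog_names) if exog_names is not None else [
            f"x{i+1}" for i in range(X.shape[1])]
        if add_intercept:
            X = np.column_stack([np.ones(len(y)), X])
            names = ["Intercept"] + names
        self.endog = y
        self.exog = X
        self.exog_names = names
        self.groups = np.asarray(groups)
        self.group_labels, self._group_idx = np.unique(self.groups,
                                                       return_inverse=True)
        counts = np.bincount(self._group_idx)
        if len(self.group_labels) >= 2 and np.sum(counts >= 2) < len(counts) / 2:
            warnings.warn("fewer than half the groups have >= 2 observations")

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, dependent: str,
                       fixed_effects, groups: str = "participant_id"):
        """Build a model from stride-table columns."""
        fixed_effects = list(fixed_effects)
        missing = [c for c in [dependent, *fixed_effects, groups]
                   if c not in table.columns]
        if missing:
            raise ValueError(f"columns not in table: {missing}")
        if len(fixed_effects) < 1:
            raise ValueError("need at least one fixed effect")
        return cls(table[dependent].to_numpy(), table[fixed_effects].to_numpy(),
                   table[groups].to_numpy(), exog_names=fixed_effects)

    # -- profiled REML machinery ------------------------------------------

    def _group_sums(self):
        idx = self._group_idx
        m = len(self.group_labels)
        X, y = self.exog, self.endog
        n_i = np.bincount(idx, minlength=m).astype(float)
        Sx = np.zeros((m, X.shape[1]))
        for j in range(X.shape[1]):
            Sx[:, j] = np.bincount(idx, weights=X[:, j], minlength=m)
        Sy = np.bincount(idx, weights=y, minlength=m)
        return n_i, Sx, Sy

    def _profile(self, lam: float, reml: bool = True):
        """GLS fit and -2 log-likelihood criterion at variance ratio lam."""
        X, y = self.exog, self.endog
        n, p = X.shape
        n_i, Sx, Sy = self._cache
        w = lam / (1.0 + lam * n_i)                       # (m,)
        XtVX = X.T @ X - (Sx * w[:, None]).T @ Sx
        XtVy = X.T @ y - (Sx * w[:, None]).T @ Sy
        beta = np.linalg.solve(XtVX, XtVy)
        r = y - X @ beta
        Sr = np.bincount(self._group_idx, weights=r,
                         minlength=len(n_i))
        rss = float(r @ r - np.sum(w * Sr ** 2))
        dof = n - p if reml else n
        sigma2_e = rss / dof
        logdet_V = float(np.sum(np.log1p(lam * n_i)))
        crit = dof * np.log(sigma2_e) + logdet_V
        if reml:
            sign, logdet_XtVX = np.linalg.slogdet(XtVX)
            crit += logdet_XtVX
        return {"lam": lam, "beta": beta, "sigma2_e": sigma2_e,
                "crit": crit, "XtVX": XtVX, "Sr": Sr, "n_i": n_i, "w": w}

    def fit(self, reml: bool = True) -> "RandomInterceptResults":
        """Fit by profiled (RE)ML; deterministic, no stochastic steps."""
        self._cache = self._group_sums()
        n, p = self.exog.shape
        if n <= p:
            raise ValueError("more parameters than observations")
        single_group = len(self.group_labels) < 2
        if single_group:
            best = self._profile(0.0, reml)
        else:
            # coarse log-spaced bracket, then high-precision bounded search
            grid = np.concatenate([[0.0], np.logspace(-8, 6, 57)])
            crits = [self._profile(l, reml)["crit"] for l in grid]
            k = int(np.argmin(crits))
            if k == 0:
                best = self._profile(0.0, reml)
            else:
                lo = grid[max(k - 1, 1)]
                hi = grid[min(k + 1, len(grid) - 1)]
                res = scipy.optimize.minimize_scalar(
                    lambda u: self._profile(np.exp(u), reml)["crit"],
                    bounds=(np.log(lo), np.log(hi)), method="bounded",
                    options={"xatol": 1e-13})
                best = self._profile(float(np.exp(res.x)), reml)
                if self._profile(0.0, reml)["crit"] < best["crit"]:
                    best = self._profile(0.0, reml)
        lam = best["lam"]
        sigma2_e = best["sigma2_e"]
        sigma2_b = lam * sigma2_e
        if sigma2_b == 0 and not single_group:
            warnings.warn("boundary fit: sigma2_b = 0 (ICC = 0)")
        cov_beta = sigma2_e * np.linalg.inv(best["XtVX"])
        blups = lam * best["Sr"] / (1.0 + lam * best["n_i"])
        fitted_fixed = self.exog @ best["beta"]
        return RandomInterceptResults(
            model=self, params=pd.Series(best["beta"],
                                         index=self.exog_names),
            cov_params=pd.DataFrame(cov_beta, index=self.exog_names,
                                    columns=self.exog_names),
            sigma2_b=float(sigma2_b), sigma2_e=float(sigma2_e),
            random_effects=pd.Series(blups, index=self.group_labels),
            fitted_fixed=fitted_fixed, reml=reml, converged=True)


@dataclasses.dataclass
class RandomInterceptResults:
    """Estimates, uncertainties, and diagnostics for a fitted model."""

    model: RandomInterceptModel
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_b: float
    sigma2_e: float
    random_effects: pd.Series
    fitted_fixed: np.ndarray
    reml: bool = True
    converged: bool = True

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params.to_numpy())),
                         index=self.params.index)

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Wald normal-approximation p-values."""
        return pd.Series(
            2 * scipy.stats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = 1.959963984540054 if alpha == 0.05 else scipy.stats.norm.ppf(
            1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse,
             "upper": self.params + z * self.bse})

    @property
    def sigma2_f(self) -> float:
        """Variance of the fixed-effect linear predictor (ddof=1)."""
        return float(np.var(self.fitted_fixed, ddof=1))

    @property
    def icc(self) -> float:
        tot = self.sigma2_b + self.sigma2_e
        return self.sigma2_b / tot if tot > 0 else 0.0

    @property
    def r2_marginal(self) -> float:
        return variance_explained(self)[0]

    @property
    def r2_conditional(self) -> float:
        return variance_explained(self)[1]

    def summary(self) -> str:
        """Human-readable fit summary (coefficients, CIs, components)."""
        ci = self.conf_int()
        lines = [
            "Random-intercept linear mixed model "
            f"({'REML' if self.reml else 'ML'})",
            f"Groups: {len(self.random_effects)}   "
            f"Observations: {len(self.model.endog)}",
            "-" * 64,
            f"{'':<22}{'coef.':>8}{'SE':>8}{'[0.025':>9}{'0.975]':>9}"
            f"{'p':>8}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<22}{self.params[name]:>8.3f}{self.bse[name]:>8.3f}"
                f"{ci.loc[name, 'lower']:>9.3f}{ci.loc[name, 'upper']:>9.3f}"
                f"{self.pvalues[name]:>8.3f}")
        r2m, r2c = variance_explained(self)
        lines += [
            "-" * 64,
            f"sigma2_b {self.sigma2_b:.4f}   sigma2_e {self.sigma2_e:.4f}   "
            f"ICC {self.icc:.3f}",
            f"Marginal R2 {r2m:.3f}   Conditional R2 {r2c:.3f}",
        ]
        return "\n".join(lines)


def variance_explained(fit: RandomInterceptResults):
    """Marginal and conditional R-squared (Nakagawa & Schielzeth form).

    marginal = s2_f / (s2_f + s2_b + s2_e);
    conditional = (s2_f + s2_b) / (s2_f + s2_b + s2_e),
    with s2_f the empirical variance of the fitted fixed-effect predictor.
    """
    s2f, s2b, s2e = fit.sigma2_f, fit.sigma2_b, fit.sigma2_e
    tot = s2f + s2b + s2e
    if tot <= 0:
        raise ValueError("all variance components are zero")
    return s2f / tot, (s2f + s2b) / tot


_SEGMENTS = ("thigh", "shank", "foot")


def rmse_fc(table: pd.DataFrame) -> pd.Series:
    """RMSE (deg) between mocap and IMU angles at FC, per segment.

    Pooled over strides and participants in the given table.
    """
    out = {}
    for seg in _SEGMENTS:
        a = table[f"theta_{seg}_fc"].to_numpy(dtype=float)
        b = table[f"theta_{seg}_imu_fc"].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        if not np.any(ok):
            raise ValueError(f"no paired FC angles for segment {seg}")
        out[seg] = float(np.sqrt(np.mean((b[ok] - a[ok]) ** 2)))
    return pd.Series(out)


_MOCAP = ["theta_thigh_fc", "theta_shank_fc", "theta_foot_fc"]
_IMU = ["theta_thigh_imu_fc", "theta_shank_imu_fc", "theta_foot_imu_fc"]

# model menu: {OS, PBF} x {TM, OG} x {mocap (A), IMU (B)}
MODEL_MENU = {
    "1A": ("TM", "overstriding_norm", _MOCAP),
    "2A": ("OG", "overstriding_norm", _MOCAP),
    "3A": ("TM", "pbf_bw", _MOCAP),
    "4A": ("OG", "pbf_bw", _MOCAP),
    "1B": ("TM", "overstriding_norm", _IMU),
    "2B": ("OG", "overstriding_norm", _IMU),
    "3B": ("TM", "pbf_bw", _IMU),
    "4B": ("OG", "pbf_bw", _IMU),
}

REDUCED_MENU = {
    "2B_thigh_shank": ("OG", "overstriding_norm", _IMU[:2]),
    "4B_thigh_shank": ("OG", "pbf_bw", _IMU[:2]),
    "4B_shank_only": ("OG", "pbf_bw", _IMU[1:2]),
    "4B_duty": ("OG", "pbf_bw", _IMU[:2] + ["duty_cycle"]),
}


def _condition_mask(table: pd.DataFrame, condition: str) -> pd.Series:
    if condition == "TM":
        return table["condition"].str.startswith("TM")
    return table["condition"] == condition


def run_model_menu(table: pd.DataFrame, menu=None, groups="participant_id"):
    """Fit the study's LMM menu on a stride table.

    All model inputs (dependent and fixed effects) are standardized as
    z-scores pooled within condition before fitting.  Returns a dict of
    menu label -> RandomInterceptResults.
    """
    menu = dict(MODEL_MENU if menu is None else menu)
    fits = {}
    for label, (cond, dep, fx) in menu.items():
        sub = table[_condition_mask(table, cond)].dropna(
            subset=[dep, *fx]).copy()
        std, _ = zscore(sub, columns=[dep, *fx])
        model = RandomInterceptModel.from_dataframe(std, dep, fx,
                                                    groups=groups)
        fits[label] = model.fit(reml=True)
    return fits


def render_model_table(fits) -> str:
    """Format a menu of fits as one coefficient grid."""
    lines = []
    for label, fit in fits.items():
        ci = fit.conf_int()
        r2m, r2c = variance_explained(fit)
        lines.append(f"LMM {label}")
        for name in fit.params.index:
            if name == "Intercept":
                continue
            lines.append(
                f"  {name:<24}{fit.params[name]:>7.2f} "
                f"[{ci.loc[name, 'lower']:>6.2f},{ci.loc[name, 'upper']:>6.2f}]"
                f"  p={fit.pvalues[name]:.3f}")
        lines.append(f"  ICC {fit.icc:.3f}  Marginal R2 {r2m:.3f}  "
                     f"Conditional R2 {r2c:.3f}")
    return "\n".join(lines)
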