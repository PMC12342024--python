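"""Noncompartmental analysis and fold-error evaluation of exposure predictions.

NCA follows the conventional IV-bolus recipe: AUClast by the
linear-up/log-down trapezoid, terminal slope (lambda_z) by log-linear
regression over the tail points chosen by best adjusted R^2, AUC and AUMC
extrapolated to infinity, and CL, Vdss, MRT derived from them. Predicted
profiles are scored against observations as observed/predicted AUClast and
Cmax ratios, summarized per distribution model as median, quartiles and
the fraction of compounds within two- and three-fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import ConcentrationProfile


@dataclass
class NcaResult:
    """Exposure metrics from one IV profile.

    auc_last/auc_inf in h*mg/L, cmax mg/L, tmax h, lambda_z 1/h,
    cl mL/min/kg, vdss mL/kg, mrt h. When no terminal decline can be
    identified (lambda_z <= 0) the extrapolated quantities are NaN.
    """

    auc_last: float
    cmax: float
    tmax: float
    auc_inf: float = np.nan
    lambda_z: float = np.nan
    cl: float = np.nan
    vdss: float = np.nan
    mrt: float = np.nan
    extrap_pct: float = np.nan


@dataclass
class FoldMetrics:
    """Observed-over-predicted exposure ratios for one compound."""

    compound_id: str
    method: str
    auc_ratio: float  # AUClast_obs / AUClast_pred
    cmax_ratio: float  # Cmax_obs / Cmax_pred

    def __post_init__(self) -> None:
        if not (self.auc_ratio > 0 and self.cmax_ratio > 0):
            raise ValueError("fold ratios must be positive")


def _trapezoid_linup_logdown(times: np.ndarray, conc: np.ndarray) -> float:
    """AUC by linear trapezoid on rising, log trapezoid on falling segments."""
    auc = 0.0
    for i in range(len(times) - 1):
        dt = times[i + 1] - times[i]
        c0, c1 = conc[i], conc[i + 1]
        if c1 < c0 and c1 > 0 and c0 > 0:
            auc += dt * (c0 - c1) / np.log(c0 / c1)
        else:
            auc += dt * (c0 + c1) / 2.0
    return auc


def _aumc_linup_logdown(times: np.ndarray, conc: np.ndarray) -> float:
    aumc = 0.0
    for i in range(len(times) - 1):
        t0, t1 = times[i], times[i + 1]
        c0, c1 = conc[i], conc[i + 1]
        dt = t1 - t0
        if c1 < c0 and c1 > 0 and c0 > 0:
            k = np.log(c0 / c1) / dt
            aumc += (t0 * c0 - t1 * c1) / k + (c0 - c1) / k**2
        else:
            aumc += dt * (t0 * c0 + t1 * c1) / 2.0
    return aumc


def _fit_lambda_z(times: np.ndarray, conc: np.ndarray) -> tuple[float, int]:
    """Terminal slope by best adjusted R^2 over the last 3..n points.

    The Cmax point itself is excluded from candidate windows. Returns
    (lambda_z, n_points); lambda_z <= 0 (or no valid window) yields NaN.
    """
    pos = conc > 0
    t, c = times[pos], conc[pos]
    if len(t) < 3:
        return np.nan, 0
    i_cmax = int(np.argmax(c))
    best = (np.nan, 0, -np.inf)
    for n_pts in range(3, len(t) + 1):
        start = len(t) - n_pts
        if start <= i_cmax:  # window would swallow Cmax
            break
        tt, cc = t[start:], np.log(c[start:])
        slope, intercept = np.polyfit(tt, cc, 1)
        resid = cc - (slope * tt + intercept)
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((cc - cc.mean()) ** 2))
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (n_pts - 1) / (n_pts - 2)
        if adj_r2 > best[2]:
            best = (-slope, n_pts, adj_r2)
    lz, n_pts, _ = best
    if not np.isfinite(lz) or lz <= 0:
        return np.nan, 0
    return float(lz), n_pts


def nca(profile: ConcentrationProfile) -> NcaResult:
    """Noncompartmental analysis of an IV-bolus plasma profile.

    Observations at or below zero are dropped (with a warning) before the
    log-down trapezoid. CL is dose/AUCinf converted to mL/min/kg, MRT is
    AUMCinf/AUCinf and Vdss = CL*MRT.
    """
    times = profile.times
    conc = profile.concentrations
    keep = conc > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} nonpositive concentration(s) before NCA")
    times, conc = times[keep], conc[keep]
    if len(conc) < 3:
        raise ValueError("NCA requires at least 3 positive concentrations")

    auc_last = _trapezoid_linup_logdown(times, conc)
    aumc_last = _aumc_linup_logdown(times, conc)
    i_cmax = int(np.argmax(conc))
    cmax, tmax = float(conc[i_cmax]), float(times[i_cmax])
    lambda_z, _ = _fit_lambda_z(times, conc)
    result = NcaResult(auc_last=float(auc_last), cmax=cmax, tmax=tmax, lambda_z=lambda_z)
    if not np.isfinite(lambda_z):
        return result

    c_last, t_last = conc[-1], times[-1]
    auc_inf = auc_last + c_last / lambda_z
    aumc_inf = aumc_last + c_last * t_last / lambda_z + c_last / lambda_z**2
    cl = profile.dose / auc_inf * 1000.0 / 60.0  # mg/kg / (h*mg/L) -> mL/min/kg
    mrt = aumc_inf / auc_inf
    result.auc_inf = float(auc_inf)
    result.extrap_pct = float(100.0 * (auc_inf - auc_last) / auc_inf)
    result.cl = float(cl)
    result.mrt = float(mrt)
    result.vdss = float(cl * mrt * 60.0)  # mL/min/kg * h -> mL/kg
    return result


def _log_interp(t: np.ndarray, times: np.ndarray, conc: np.ndarray) -> np.ndarray:
    """Interpolate a profile to new times, log-linearly where positive."""
    if np.all(conc > 0):
        return np.exp(np.interp(t, times, np.log(conc)))
    return np.interp(t, times, conc)


def fold_metrics(
    obs: ConcentrationProfile, pred: ConcentrationProfile, method: str = ""
) -> FoldMetrics:
    """Observed/predicted AUClast and Cmax ratios on the common time window.

    Both AUCs are evaluated on the union of the two time grids restricted
    to the overlapping window, with each profile interpolated (log-linearly
    where possible) to that grid; Cmax is taken over the observed times.
    """
    t_lo = max(obs.times[0], pred.times[0])
    t_hi = min(obs.times[-1], pred.times[-1])
    if t_hi <= t_lo:
        raise ValueError("observed and predicted time ranges do not overlap")
    union = np.unique(np.concatenate([obs.times, pred.times]))
    union = union[(union >= t_lo) & (union <= t_hi)]
    c_obs = _log_interp(union, obs.times, obs.concentrations)
    c_pred = _log_interp(union, pred.times, pred.concentrations)
    auc_obs = _trapezoid_linup_logdown(union, c_obs)
    auc_pred = _trapezoid_linup_logdown(union, c_pred)
    obs_window = (obs.times >= t_lo) & (obs.times <= t_hi)
    cmax_obs = float(np.max(obs.concentrations[obs_window]))
    cmax_pred = float(np.max(_log_interp(obs.times[obs_window], pred.times, pred.concentrations)))
    return FoldMetrics(
        compound_id=obs.compound_id or pred.compound_id,
        method=method,
        auc_ratio=auc_obs / auc_pred,
        cmax_ratio=cmax_obs / cmax_pred,
    )


def summarize(metrics: list[FoldMetrics] | pd.DataFrame, group_by: str = "method") -> pd.DataFrame:
    """Per-group median, quartiles and 2-/3-fold fractions of the ratios.

    Quantiles use linear interpolation (type 7). Returns one row per
    (group, metric) with columns median, q1, q3, pct_within_2fold,
    pct_within_3fold, n.
    """
    if not isinstance(metrics, pd.DataFrame):
        if not metrics:
            raise ValueError("summarize requires at least one FoldMetrics")
        metrics = pd.DataFrame(
            [
                {
                    "compound_id": m.compound_id,
                    group_by: getattr(m, group_by),
                    "auc_ratio": m.auc_ratio,
                    "cmax_ratio": m.cmax_ratio,
                }
                for m in metrics
            ]
        )
    rows = []
    for group, sub in metrics.groupby(group_by, sort=True):
        for metric in ("auc_ratio", "cmax_ratio"):
            vals = sub[metric].to_numpy()
            rows.append(
                {
                    group_by: group,
                    "metric": metric,
                    "median": float(np.quantile(vals, 0.5)),
                    "q1": float(np.quantile(vals, 0.25)),
                    "q3": float(np.quantile(vals, 0.75)),
                    "pct_within_2fold": float(np.mean((vals >= 0.5) & (vals <= 2.0))),
                    "pct_within_3fold": float(np.mean((vals >= 1 / 3) & (vals <= 3.0))),
                    "n": int(len(vals)),
                }
            )
    return pd.DataFrame(rows)
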