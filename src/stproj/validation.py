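"""Cross-validation protocol, error metrics, and the STP-vs-STOK experiment.

Both estimation routes are run fold by fold on identical random
partitions; covariance models (and, for the projection route, the
representative spread speed) are re-fitted inside each training fold so
no information leaks from held-out records.  Errors are reported on the
back-transformed incidence scale (per 100,000).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import covariance as cov
from . import kriging as krig
from . import preprocess as pre
from . import projection as proj
from .config import RunConfig

__all__ = [
    "ErrorSummary",
    "kfold_split",
    "grouped_kfold_split",
    "error_summary",
    "cross_validate",
    "compare_stp_stok",
    "projected_range_experiment",
    "coefficient_of_variation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorSummary:
    """ME / MAE / RMSE on the incidence-per-100,000 scale."""

    me: float
    mae: float
    rmse: float
    n: int


def kfold_split(n: int, k: int = 10, seed: int = 0) -> np.ndarray:
    """Uniform random partition of ``n`` records into folds ``1..k``.

    Fold sizes differ by at most one; deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if n < k:
        raise ValueError("need at least k records")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k + 1
    rng.shuffle(folds)
    return folds


def grouped_kfold_split(group_ids, k: int = 10, seed: int = 0) -> np.ndarray:
    """Random k-fold partition that keeps all records of a group in one fold.

    Useful for frozen fields with zero spread speed, where records of the
    same location are duplicated across years and record-level folds
    would leak the held-out values verbatim.
    """
    group_ids = pd.Series(group_ids).reset_index(drop=True)
    groups = group_ids.unique()
    if k < 2 or len(groups) < k:
        raise ValueError("need k >= 2 and at least k distinct groups")
    rng = np.random.default_rng(seed)
    folds = np.arange(len(groups)) % k + 1
    rng.shuffle(folds)
    return group_ids.map(dict(zip(groups, folds))).to_numpy()


def error_summary(true: np.ndarray, est: np.ndarray) -> ErrorSummary:
    """ME = mean(est - true), MAE = mean|est - true|, RMSE = sqrt(mean((est - true)^2))."""
    true = np.asarray(true, dtype=float)
    est = np.asarray(est, dtype=float)
    if true.shape != est.shape or true.size < 1:
        raise ValueError("true and est must be equal-length, nonempty")
    err = est - true
    return ErrorSummary(
        me=float(err.mean()),
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        n=int(err.size),
    )


def coefficient_of_variation(mean: float, sd: float) -> float:
    """SD over mean, as a percentage rounded to two decimals."""
    if mean == 0:
        raise ValueError("coefficient of variation is undefined for mean 0")
    return round(100.0 * sd / mean, 2)


def _stp_fold(
    train: pd.DataFrame, test: pd.DataFrame, cfg: RunConfig, t0: float
) -> tuple[np.ndarray, dict]:
    """Full projection pipeline on one fold; returns incidence estimates at test rows."""
    tr = pre.detrend(
        train, cfg.detrend_spatial_radius_m, cfg.detrend_temporal_radius_yr
    )
    grid_st = cov.empirical_covariance(
        tr[["x_m", "y_m"]].to_numpy(),
        tr["residual"].to_numpy(),
        years=tr["year"].to_numpy(),
        spatial_bin_m=cfg.cov_spatial_bin_m,
        max_spatial_m=cfg.cov_max_spatial_m,
        temporal_bin_yr=cfg.cov_temporal_bin_yr,
        max_temporal_yr=cfg.cov_max_temporal_yr,
    )
    sep_fit = cov.fit_model(grid_st, "separable_gaussian_exponential")
    vel = proj.representative_velocity(
        grid_st, sep_fit.model, cfg.velocity_strategy, records=tr,
        mode=cfg.projection_mode,
        direction=None if cfg.projection_mode == "literal" else np.asarray(cfg.projection_direction),
    )

    p_train = proj.project_coordinates(
        tr[["x_m", "y_m"]].to_numpy(), tr["year"].to_numpy(), vel, t0
    )
    p_test = proj.project_coordinates(
        test[["x_m", "y_m"]].to_numpy(), test["year"].to_numpy(), vel, t0
    )

    logv = tr["log_value"].to_numpy()
    trend_train = pre.window_trend(p_train, p_train, logv, cfg.projected_detrend_radius_m)
    resid = logv - trend_train
    grid_p = cov.empirical_covariance(
        p_train,
        resid,
        spatial_bin_m=cfg.cov_spatial_bin_m,
        max_spatial_m=cfg.cov_max_spatial_m,
    )
    proj_fit = cov.fit_model(grid_p, "projected_exponential")

    est = krig.stp_krige(p_test, p_train, resid, proj_fit.model, cfg.kriging())
    trend_test = pre.window_trend(p_test, p_train, logv, cfg.projected_detrend_radius_m)
    log_est = est["estimate"].to_numpy() + trend_test
    meta = {
        "velocity_m_per_yr": vel.speed,
        "velocity_strategy": vel.strategy,
        "projection_mode": vel.mode,
        "t0": t0,
        "separable_fit": sep_fit.params,
        "projected_fit": proj_fit.params,
    }
    return pre.inverse_log_transform(log_est), meta


def _stok_fold(
    train: pd.DataFrame, test: pd.DataFrame, cfg: RunConfig
) -> tuple[np.ndarray, dict]:
    """Space-time ordinary kriging pipeline on one fold."""
    tr = pre.detrend(
        train, cfg.detrend_spatial_radius_m, cfg.detrend_temporal_radius_yr
    )
    grid_st = cov.empirical_covariance(
        tr[["x_m", "y_m"]].to_numpy(),
        tr["residual"].to_numpy(),
        years=tr["year"].to_numpy(),
        spatial_bin_m=cfg.cov_spatial_bin_m,
        max_spatial_m=cfg.cov_max_spatial_m,
        temporal_bin_yr=cfg.cov_temporal_bin_yr,
        max_temporal_yr=cfg.cov_max_temporal_yr,
    )
    sep_fit = cov.fit_model(grid_st, "separable_gaussian_exponential")

    data_st = tr[["x_m", "y_m", "year"]].to_numpy(dtype=float)
    test_st = test[["x_m", "y_m", "year"]].to_numpy(dtype=float)
    est = krig.stok_krige(
        test_st, data_st, tr["residual"].to_numpy(), sep_fit.model, cfg.kriging()
    )
    trend_test = pre.window_trend(
        test_st[:, :2],
        data_st[:, :2],
        tr["log_value"].to_numpy(),
        cfg.detrend_spatial_radius_m,
        query_t=test_st[:, 2],
        ref_t=data_st[:, 2],
        temporal_radius=cfg.detrend_temporal_radius_yr,
    )
    log_est = est["estimate"].to_numpy() + trend_test
    meta = {"separable_fit": sep_fit.params}
    return pre.inverse_log_transform(log_est), meta


def cross_validate(
    records: pd.DataFrame,
    method: str,
    cfg: RunConfig = RunConfig(),
    *,
    folds: np.ndarray | None = None,
) -> tuple[ErrorSummary, pd.DataFrame, dict]:
    """k-fold cross-validation of one estimation route.

    Returns the pooled error summary on the incidence scale, a
    per-record table (true, est, fold), and run metadata.  Held-out
    records are never visible to detrending, covariance fitting,
    velocity estimation, or kriging within their fold.
    """
    if method not in ("stp", "stok"):
        raise ValueError(f"unknown method {method!r}")
    records = records.reset_index(drop=True)
    if folds is None:
        folds = kfold_split(len(records), cfg.n_folds, cfg.seed)
    t0 = float(records["year"].min())
    est = np.full(len(records), np.nan)
    meta: dict = {"method": method, "folds": int(folds.max())}
    for f in np.unique(folds):
        train = records.loc[folds != f]
        test = records.loc[folds == f]
        if method == "stp":
            vals, fold_meta = _stp_fold(train, test, cfg, t0)
        else:
            vals, fold_meta = _stok_fold(train, test, cfg)
        est[folds == f] = vals
        meta[f"fold_{int(f)}"] = fold_meta
    true = records["incidence_per_1e5"].to_numpy(dtype=float)
    report = pd.DataFrame(
        {
            "town_id": records["town_id"],
            "year": records["year"],
            "true_per_1e5": true,
            "est_per_1e5": est,
            "fold": folds,
            "method": method,
        }
    )
    return error_summary(true, est), report, meta


def compare_stp_stok(
    records: pd.DataFrame, cfg: RunConfig = RunConfig(), *, group_by_town: bool = False
) -> dict:
    """Run both routes on identical folds and return their error summaries."""
    records = records.reset_index(drop=True)
    if group_by_town:
        folds = grouped_kfold_split(records["town_id"], cfg.n_folds, cfg.seed)
    else:
        folds = kfold_split(len(records), cfg.n_folds, cfg.seed)
    out: dict = {}
    reports = []
    for method in ("stp", "stok"):
        summary, report, meta = cross_validate(records, method, cfg, folds=folds)
        out[method] = summary
        out[f"{method}_meta"] = meta
        reports.append(report)
    out["records"] = pd.concat(reports, ignore_index=True)
    return out


def projected_range_experiment(
    records: pd.DataFrame, cfg: RunConfig = RunConfig()
) -> dict:
    """Fit the projected-domain range with and without the coordinate transform.

    Returns the fitted projected exponential range (``alpha_projected``),
    the spatial range of the separable space-time fit
    (``alpha_spacetime_spatial``), the exponential range fitted with the
    identity projection (``alpha_identity``), and the estimated speed.
    """
    tr = pre.detrend(
        records, cfg.detrend_spatial_radius_m, cfg.detrend_temporal_radius_yr
    )
    grid_st = cov.empirical_covariance(
        tr[["x_m", "y_m"]].to_numpy(),
        tr["residual"].to_numpy(),
        years=tr["year"].to_numpy(),
        spatial_bin_m=cfg.cov_spatial_bin_m,
        max_spatial_m=cfg.cov_max_spatial_m,
        temporal_bin_yr=cfg.cov_temporal_bin_yr,
        max_temporal_yr=cfg.cov_max_temporal_yr,
    )
    sep_fit = cov.fit_model(grid_st, "separable_gaussian_exponential")
    vel = proj.representative_velocity(
        grid_st, sep_fit.model, cfg.velocity_strategy, records=tr
    )
    t0 = float(tr["year"].min())
    logv = tr["log_value"].to_numpy()

    def exp_range(vel_result) -> float:
        p = proj.project_coordinates(
            tr[["x_m", "y_m"]].to_numpy(), tr["year"].to_numpy(), vel_result, t0
        )
        resid = logv - pre.window_trend(p, p, logv, cfg.projected_detrend_radius_m)
        grid_p = cov.empirical_covariance(
            p, resid,
            spatial_bin_m=cfg.cov_spatial_bin_m,
            max_spatial_m=cfg.cov_max_spatial_m,
        )
        return cov.fit_model(grid_p, "projected_exponential").params["alpha"]

    return {
        "alpha_projected": exp_range(vel),
        "alpha_spacetime_spatial": sep_fit.params["alpha_s"],
        "alpha_identity": exp_range(proj.VelocityResult(speed=0.0, strategy="fixed:0")),
        "speed_m_per_yr": vel.speed,
        "separable_fit": sep_fit.params,
    }
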