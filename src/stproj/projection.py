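"""The projection core: spread-velocity algebra and coordinate transforms.

A traveling random field satisfies ``Z(s, t) = Z(s - v t, 0)``; the
separable space-time covariance model then implies, lag pair by lag
pair, a quadratic in the scalar spread speed ``v``:

    ``alpha_t * tau * v^2 - 2 * alpha_t * |h| * v - alpha_s^2 = 0``

whose admissible root (the one keeping the projected lag
``r_hat = |h| - v tau`` positive) is

    ``v = |h| / tau - (alpha_s / tau) * sqrt(|h|^2 / alpha_s^2 + tau / alpha_t)``.

This module solves that quadratic, evaluates the induced projected lag,
collapses the pairwise velocity surface into a single representative
speed, and applies / inverts the coordinate transform
``s_hat = s - v (t - t0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .covariance import LagBinGrid, SeparableCovModel

__all__ = [
    "VelocityResult",
    "solve_velocity",
    "projected_lag",
    "velocity_surface",
    "representative_velocity",
    "project_coordinates",
    "backproject_coordinates",
    "backtransform_estimates",
]


@dataclass
class VelocityResult:
    """A representative spread speed plus the conventions used to apply it.

    ``mode='literal'`` subtracts the signed scalar ``speed * (t - t0)``
    from each planar coordinate (a fixed diagonal displacement);
    ``mode='vector'`` displaces by ``|speed| * (t - t0)`` along the unit
    ``direction`` vector.
    """

    speed: float
    mode: str = "literal"
    direction: Optional[np.ndarray] = None
    strategy: str = "paircount_mean"
    source_lags: Optional[pd.DataFrame] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.speed):
            raise ValueError("velocity speed must be finite")
        if self.mode not in ("literal", "vector"):
            raise ValueError(f"unknown projection mode {self.mode!r}")
        if self.mode == "vector":
            if self.direction is None:
                raise ValueError("vector mode requires a direction")
            d = np.asarray(self.direction, dtype=float)
            if d.shape != (2,) or not np.isclose(np.linalg.norm(d), 1.0):
                raise ValueError("direction must be a 2-D unit vector")
            self.direction = d


def solve_velocity(h, tau, model: SeparableCovModel):
    """Admissible root of the spread-speed quadratic at lag ``(|h|, tau)``.

    Returns the signed speed in m/yr; always the root for which the
    projected lag ``|h| - v * tau`` is positive.  Singular at
    ``tau = 0``.
    """
    h = np.asarray(h, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError(
            "solve_velocity requires tau > 0: the speed quadratic is singular at tau = 0"
        )
    a_s, a_t = model.alpha_s, model.alpha_t
    v = h / tau - (a_s / tau) * np.sqrt(h**2 / a_s**2 + tau / a_t)
    return v if v.ndim else float(v)


def projected_lag(h, tau, model: SeparableCovModel):
    """Projected scalar lag ``r_hat = alpha_s * sqrt(|h|^2/alpha_s^2 + tau/alpha_t)``.

    Equals ``|h|`` at ``tau = 0`` and ``|h| - v tau`` for the admissible
    speed ``v`` at ``tau > 0``; strictly positive whenever ``tau > 0``.
    """
    h = np.asarray(h, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("projected_lag requires tau >= 0")
    r = model.alpha_s * np.sqrt(h**2 / model.alpha_s**2 + tau / model.alpha_t)
    return r if r.ndim else float(r)


def velocity_surface(
    model: SeparableCovModel, h_grid, tau_grid
) -> pd.DataFrame:
    """Speed surface over a grid of lags, long format (h_m, tau_yr, velocity_m_per_yr)."""
    h_grid = np.asarray(h_grid, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if np.any(tau_grid <= 0):
        raise ValueError("velocity_surface requires all tau > 0")
    hh, tt = np.meshgrid(h_grid, tau_grid, indexing="ij")
    vv = solve_velocity(hh.ravel(), tt.ravel(), model)
    return pd.DataFrame(
        {"h_m": hh.ravel(), "tau_yr": tt.ravel(), "velocity_m_per_yr": vv}
    )


def _variogram_match_speed(
    records: pd.DataFrame,
    v_bracket: float,
    *,
    match_radius_m: float = 5_000.0,
    n_candidates: int = 41,
) -> float:
    """Speed minimizing the cross-year variogram at short projected distance.

    For every pair of residuals observed in different years, the literal
    transform moves their separation to ``(dx - v dt, dy - v dt)``; the
    speed that best realigns the traveling pattern minimizes the mean
    squared residual difference among pairs that end up within
    ``match_radius_m`` of each other.  Candidates span
    ``[-|v_bracket|, |v_bracket|]`` symmetrically.
    """
    xy = records[["x_m", "y_m"]].to_numpy(dtype=float)
    yr = records["year"].to_numpy(dtype=float)
    z = records["residual"].to_numpy(dtype=float)
    ii, jj = np.triu_indices(len(z), k=1)
    dt = yr[ii] - yr[jj]
    cross = dt != 0
    ii, jj, dt = ii[cross], jj[cross], dt[cross]
    if len(ii) == 0:
        raise ValueError("variogram_match needs records in at least two years")
    dx = xy[ii, 0] - xy[jj, 0]
    dy = xy[ii, 1] - xy[jj, 1]
    dz2 = (z[ii] - z[jj]) ** 2
    r2 = match_radius_m**2
    best = None
    for v in np.linspace(-abs(v_bracket), abs(v_bracket), n_candidates):
        d2 = (dx - v * dt) ** 2 + (dy - v * dt) ** 2
        mask = d2 <= r2
        if mask.sum() < 30:
            continue
        gamma = float(dz2[mask].mean())
        if best is None or gamma < best[0]:
            best = (gamma, float(v))
    if best is None:
        raise ValueError(
            "variogram_match found no candidate speed with enough close "
            f"cross-year pairs (radius {match_radius_m} m)"
        )
    return best[1]


def representative_velocity(
    grid: LagBinGrid,
    model: SeparableCovModel,
    strategy: str = "paircount_mean",
    *,
    records: Optional[pd.DataFrame] = None,
    mode: str = "literal",
    direction: Optional[np.ndarray] = None,
    match_radius_m: float = 5_000.0,
) -> VelocityResult:
    """Collapse the pairwise speed surface into a single projection speed.

    ``paircount_mean`` (default) evaluates the admissible speed at every
    nonempty lag bin with ``tau > 0`` and averages, weighting by pair
    count; ``median`` takes the unweighted median over those bins;
    ``variogram_match`` scans candidate speeds (bracketed by 1.5x the
    steepest surface speed) and picks the one minimizing the cross-year
    residual variogram at short projected range — it needs the residual
    ``records`` and is the recommended strategy for actual estimation;
    ``fixed:<value>`` returns the given speed regardless of the grid.
    """
    if strategy.startswith("fixed:"):
        speed = float(strategy.split(":", 1)[1])
        return VelocityResult(
            speed=speed, mode=mode, direction=direction, strategy=strategy
        )

    if not grid.temporal:
        raise ValueError("representative_velocity requires a space-time lag grid")
    bins = grid.nonempty()
    bins = bins[bins["tau"] > 0].reset_index(drop=True)
    if len(bins) == 0:
        raise ValueError("no nonempty lag bins with tau > 0; cannot estimate a speed")

    v = solve_velocity(bins["h"].to_numpy(), bins["tau"].to_numpy(), model)
    bins = bins.assign(velocity_m_per_yr=v)
    if strategy == "paircount_mean":
        w = bins["count"].to_numpy().astype(float)
        speed = float(np.sum(w * v) / np.sum(w))
    elif strategy == "median":
        speed = float(np.median(v))
    elif strategy == "variogram_match":
        if records is None:
            raise ValueError("variogram_match requires the residual records")
        bracket = 1.5 * solve_velocity(0.0, float(bins["tau"].min()), model)
        speed = _variogram_match_speed(
            records, bracket, match_radius_m=match_radius_m
        )
    else:
        raise ValueError(f"unknown velocity strategy {strategy!r}")
    return VelocityResult(
        speed=speed, mode=mode, direction=direction, strategy=strategy, source_lags=bins
    )


def project_coordinates(
    xy: np.ndarray, t: np.ndarray, velocity: VelocityResult, t0: float
) -> np.ndarray:
    """Map ``(s, t)`` points to projected planar points ``s_hat``.

    Literal mode: ``s_hat_i = s_i - speed * (t - t0)`` for both axes.
    Vector mode: ``s_hat = s - |speed| * (t - t0) * direction``.
    Invertible given the same velocity and reference time.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    t = np.asarray(t, dtype=float)
    dt = (t - t0).reshape(-1, 1)
    if velocity.mode == "literal":
        return xy - velocity.speed * dt
    return xy - abs(velocity.speed) * dt * velocity.direction[None, :]


def backproject_coordinates(
    xy_hat: np.ndarray, t: np.ndarray, velocity: VelocityResult, t0: float
) -> np.ndarray:
    """Inverse of :func:`project_coordinates` for the same ``(velocity, t0)``."""
    xy_hat = np.atleast_2d(np.asarray(xy_hat, dtype=float))
    t = np.asarray(t, dtype=float)
    dt = (t - t0).reshape(-1, 1)
    if velocity.mode == "literal":
        return xy_hat + velocity.speed * dt
    return xy_hat + abs(velocity.speed) * dt * velocity.direction[None, :]


def backtransform_estimates(estimates: dict, image_of: dict) -> dict:
    """Relabel estimates at projected points back onto ``(s, t)`` points.

    ``image_of`` maps each original space-time point key to its projected
    point key; the value estimated at the image is returned unchanged at
    the original point.  Pure relabeling — no interpolation.
    """
    missing = [k for k, v in image_of.items() if v not in estimates]
    if missing:
        raise KeyError(f"no estimate at the projected image of {missing[:3]}")
    return {st: estimates[image_of[st]] for st in image_of}
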