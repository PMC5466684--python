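"""Traveling-random-field simulator and synthetic study layouts.

The latent log-scale field is drawn once, exactly, on the projected
coordinates ``s_hat = s - v t``: the covariance matrix over all distinct
projected points is factorized (Cholesky, a matrix square root) and
multiplied into a standard-normal vector.  Reading the field off at
every ``(s, t)`` then satisfies the frozen-field identity
``Z(s, t) = Z(s - v t, 0)`` exactly, because coincident projected
points share a single draw.  A planar log-scale trend and the
``exp(y) - 1`` back-transform to the incidence scale are applied on
top.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Extent",
    "SimulationConfig",
    "SimulatedField",
    "generate_layout",
    "simulate_traveling_field",
    "generate_age_structure",
]

_SQRT2 = float(np.sqrt(2.0))


@dataclass(frozen=True)
class Extent:
    """Planar rectangle in metres."""

    x_min: float = 0.0
    y_min: float = 0.0
    x_max: float = 100_000.0
    y_max: float = 100_000.0

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError("extent must have positive area")

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)


@dataclass(frozen=True)
class SimulationConfig:
    n_locations: int = 200
    years: Sequence[int] = (2008, 2009, 2010, 2011, 2012)
    extent: Extent = field(default_factory=Extent)
    speed: float = 0.0  # m/yr, signed, along `direction`
    direction: tuple = (1.0 / _SQRT2, 1.0 / _SQRT2)  # unit vector, default SW->NE
    cov_family: str = "gaussian"
    sill: float = 1.0
    range_m: float = 15_000.0
    trend_amplitude: float = 0.0  # log-incidence units along `trend_direction`
    trend_direction: tuple = (1.0 / _SQRT2, 1.0 / _SQRT2)
    mean_log: float = 3.0  # baseline log(incidence+1) level
    min_separation_m: float = 500.0
    jitter_factor: float = 1e-10  # diagonal jitter = jitter_factor * sill
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("n_locations must be >= 2")
        if len(self.years) < 1:
            raise ValueError("at least one year is required")
        if self.range_m <= 0 or self.sill <= 0:
            raise ValueError("range_m and sill must be > 0")
        if self.cov_family not in ("gaussian", "exponential"):
            raise ValueError(f"unknown cov_family {self.cov_family!r}")
        for name in ("direction", "trend_direction"):
            d = np.asarray(getattr(self, name), dtype=float)
            if d.shape != (2,) or not np.isclose(np.linalg.norm(d), 1.0):
                raise ValueError(f"{name} must be a 2-D unit vector")


@dataclass
class SimulatedField:
    records: pd.DataFrame
    true_params: SimulationConfig
    latent_values: np.ndarray  # latent field per record, aligned with records
    projected_xy: np.ndarray  # projected coordinates per record


def generate_layout(
    n: int,
    extent: Extent,
    seed: int,
    *,
    min_separation_m: float = 500.0,
    max_attempts: int = 200,
) -> np.ndarray:
    """Scatter ``n`` distinct points uniformly in ``extent``.

    Rejection sampling enforces a minimum pairwise separation;
    deterministic given the seed.
    """
    if n < 2:
        raise ValueError("a layout needs n >= 2 locations")
    # crude disc-packing feasibility bound
    if n * np.pi * (min_separation_m / 2.0) ** 2 > 0.91 * extent.area:
        raise ValueError(
            f"extent too small to place {n} points at minimum separation "
            f"{min_separation_m} m"
        )
    rng = np.random.default_rng(seed)
    pts: list[np.ndarray] = []
    for _ in range(max_attempts):
        need = n - len(pts)
        if need == 0:
            break
        cand = np.column_stack(
            [
                rng.uniform(extent.x_min, extent.x_max, size=4 * need),
                rng.uniform(extent.y_min, extent.y_max, size=4 * need),
            ]
        )
        for p in cand:
            if len(pts) == n:
                break
            if pts:
                d2 = np.sum((np.asarray(pts) - p) ** 2, axis=1)
                if d2.min() < min_separation_m**2:
                    continue
            pts.append(p)
    if len(pts) < n:
        raise ValueError(
            f"could not place {n} points at minimum separation {min_separation_m} m "
            f"after {max_attempts} sampling rounds"
        )
    return np.asarray(pts)


def _cov_matrix(points: np.ndarray, config: SimulationConfig) -> np.ndarray:
    d = squareform(pdist(points))
    if config.cov_family == "gaussian":
        cov = config.sill * np.exp(-3.0 * d**2 / config.range_m**2)
    else:
        cov = config.sill * np.exp(-3.0 * d / config.range_m)
    return cov


def simulate_traveling_field(config: SimulationConfig) -> SimulatedField:
    """Draw one realization of the traveling incidence field.

    Returns records with columns ``town_id, x_m, y_m, year,
    incidence_per_1e5`` (plus the latent/log diagnostics); exactly
    ``n_locations * len(years)`` rows, reproducible bit-for-bit from the
    seed.
    """
    xy = generate_layout(
        config.n_locations,
        config.extent,
        config.seed,
        min_separation_m=config.min_separation_m,
    )
    years = np.asarray(sorted(config.years), dtype=int)
    t0 = float(years.min())
    u = np.asarray(config.direction, dtype=float)

    n_loc, n_yr = config.n_locations, len(years)
    rec_xy = np.repeat(xy, n_yr, axis=0)
    rec_year = np.tile(years, n_loc)
    dt = (rec_year - t0).astype(float)
    proj = rec_xy - config.speed * dt[:, None] * u[None, :]

    # one draw per distinct projected point; coincident projections share it
    key = np.round(proj, 6)
    uniq, inverse = np.unique(key, axis=0, return_inverse=True)
    cov = _cov_matrix(uniq, config)
    cov[np.diag_indices_from(cov)] += config.jitter_factor * config.sill
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "projected-point covariance matrix is not positive definite "
            "even after diagonal jitter"
        ) from exc
    rng = np.random.default_rng(config.seed + 1)
    latent_uniq = chol @ rng.standard_normal(len(uniq))
    latent = latent_uniq[inverse]

    span = np.hypot(
        config.extent.x_max - config.extent.x_min,
        config.extent.y_max - config.extent.y_min,
    )
    origin = np.array([config.extent.x_min, config.extent.y_min])
    along = (rec_xy - origin) @ np.asarray(config.trend_direction, dtype=float)
    trend = config.mean_log + config.trend_amplitude * along / span

    log_value = trend + latent
    incidence = np.maximum(np.expm1(log_value), 0.0)

    town_ids = np.repeat(
        [f"t{i:04d}" for i in range(n_loc)], n_yr
    )
    records = pd.DataFrame(
        {
            "town_id": town_ids,
            "x_m": rec_xy[:, 0],
            "y_m": rec_xy[:, 1],
            "year": rec_year,
            "incidence_per_1e5": incidence,
            "latent": latent,
            "log_value": log_value,
            "true_trend": trend,
        }
    )
    return SimulatedField(
        records=records,
        true_params=replace(config),
        latent_values=latent,
        projected_xy=proj,
    )


def generate_age_structure(
    n_locations: int,
    strata: Sequence[str],
    seed: int,
    *,
    totals: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Positive integer populations per location x age stratum.

    Each stratum total (default 10,000 per location on average) is dealt
    across locations by a multinomial after guaranteeing one person per
    cell; column sums equal the requested totals exactly.
    """
    if len(strata) < 1:
        raise ValueError("at least one age stratum is required")
    if totals is None:
        totals = [10_000 * n_locations] * len(strata)
    if len(totals) != len(strata):
        raise ValueError("totals must match strata")
    if any(t < n_locations for t in totals):
        raise ValueError("each stratum total must be >= n_locations (positivity)")
    rng = np.random.default_rng(seed)
    cols = {}
    for s, total in zip(strata, totals):
        extra = rng.multinomial(total - n_locations, np.full(n_locations, 1.0 / n_locations))
        cols[s] = extra + 1
    df = pd.DataFrame(cols, index=[f"t{i:04d}" for i in range(n_locations)])
    df.index.name = "town_id"
    return df
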