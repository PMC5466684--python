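"""Ordinary kriging engine for the projected planar domain and for space-time.

One augmented-system solver serves both routes.  Neighborhoods are
selected inside the configured search radii and ranked by covariance to
the target (highest first) — for a purely spatial monotone model this
coincides with distance ranking, and for space-time data it avoids
inventing a composite space-time metric.  Exact duplicate coordinates
are averaged before solving to keep the system nonsingular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .covariance import ProjectedCovModel, SeparableCovModel

__all__ = ["KrigingConfig", "KrigingEstimate", "ok_estimate", "stp_krige", "stok_krige"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class KrigingConfig:
    max_neighbors: int = 50
    spatial_search_radius_m: float = 10_000.0
    temporal_search_radius_yr: float = 2.0
    min_neighbors: int = 3
    nugget: float = 0.0
    max_radius_expansions: int = 3

    def __post_init__(self) -> None:
        if not (self.max_neighbors >= self.min_neighbors >= 1):
            raise ValueError("need max_neighbors >= min_neighbors >= 1")
        if self.spatial_search_radius_m <= 0 or self.temporal_search_radius_yr <= 0:
            raise ValueError("search radii must be > 0")


@dataclass
class KrigingEstimate:
    value: float
    variance: float
    n_neighbors_used: int
    weights: np.ndarray = field(repr=False)
    neighbor_index: np.ndarray = field(repr=False)
    lagrange: float = 0.0


def _solve_augmented(
    C: np.ndarray, c_vec: np.ndarray, values: np.ndarray, sill: float
) -> tuple[float, float, np.ndarray, float]:
    """Solve the ordinary-kriging system [C 1; 1' 0][w; mu] = [c; 1]."""
    n = len(values)
    K = np.empty((n + 1, n + 1))
    K[:n, :n] = C
    K[:n, n] = 1.0
    K[n, :n] = 1.0
    K[n, n] = 0.0
    rhs = np.append(c_vec, 1.0)
    try:
        sol = np.linalg.solve(K, rhs)
    except np.linalg.LinAlgError:
        K[:n, :n] += np.eye(n) * (1e-10 * sill)
        try:
            sol = np.linalg.solve(K, rhs)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular kriging system after deduplication and jitter "
                f"({n} neighbors)"
            ) from exc
    w, mu = sol[:n], sol[n]
    est = float(w @ values)
    var = float(sill - w @ c_vec - mu)
    if var < 0:
        var = 0.0 if var > -1e-6 * sill else var
    return est, var, w, float(mu)


def ok_estimate(
    target_cov: np.ndarray,
    neighbor_cov: np.ndarray,
    values: np.ndarray,
    sill: float,
    neighbor_index: Optional[np.ndarray] = None,
) -> KrigingEstimate:
    """Ordinary kriging from precomputed covariances.

    ``neighbor_cov`` is the covariance matrix among the selected data,
    ``target_cov`` the covariance vector between target and data, and
    ``sill`` the model covariance at zero lag (used for the variance).
    """
    values = np.asarray(values, dtype=float)
    est, var, w, mu = _solve_augmented(
        np.asarray(neighbor_cov, dtype=float),
        np.asarray(target_cov, dtype=float),
        values,
        sill,
    )
    if neighbor_index is None:
        neighbor_index = np.arange(len(values))
    return KrigingEstimate(
        value=est,
        variance=var,
        n_neighbors_used=len(values),
        weights=w,
        neighbor_index=np.asarray(neighbor_index),
        lagrange=mu,
    )


def _dedup(coords: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average values at exactly duplicated coordinates."""
    uniq, inverse = np.unique(coords, axis=0, return_inverse=True)
    if len(uniq) == len(coords):
        return coords, values
    sums = np.zeros(len(uniq))
    cnt = np.zeros(len(uniq))
    np.add.at(sums, inverse, values)
    np.add.at(cnt, inverse, 1.0)
    log.info("averaged %d duplicate coordinates before kriging", len(coords) - len(uniq))
    return uniq, sums / cnt


def _select_and_solve(
    cov_to_target: np.ndarray,
    in_radius: Callable[[float], np.ndarray],
    cov_matrix_of: Callable[[np.ndarray], np.ndarray],
    values: np.ndarray,
    sill: float,
    config: KrigingConfig,
) -> KrigingEstimate:
    factor = 1.0
    for attempt in range(config.max_radius_expansions + 1):
        idx = np.nonzero(in_radius(factor))[0]
        if len(idx) >= config.min_neighbors:
            break
        factor *= 2.0
        if attempt < config.max_radius_expansions:
            log.info("fewer than %d neighbors; doubling search radii", config.min_neighbors)
    else:
        idx = np.array([], dtype=int)
    if len(idx) < config.min_neighbors:
        raise ValueError(
            f"only {len(idx)} neighbors found after {config.max_radius_expansions} "
            f"radius expansions (min_neighbors={config.min_neighbors})"
        )
    # rank by covariance to the target, highest first; stable index tie-break
    order = np.lexsort((idx, -cov_to_target[idx]))
    idx = idx[order][: config.max_neighbors]
    C = cov_matrix_of(idx)
    if config.nugget > 0:
        C = C + np.eye(len(idx)) * config.nugget
    return ok_estimate(cov_to_target[idx], C, values[idx], sill + config.nugget, idx)


def stp_krige(
    targets_xy: np.ndarray,
    data_xy: np.ndarray,
    values: np.ndarray,
    model: ProjectedCovModel,
    config: KrigingConfig = KrigingConfig(),
) -> pd.DataFrame:
    """Ordinary kriging in the projected planar domain.

    ``data_xy`` / ``targets_xy`` are projected coordinates (metres);
    returns one row per target with columns estimate, variance,
    n_neighbors.
    """
    targets_xy = np.atleast_2d(np.asarray(targets_xy, dtype=float))
    data_xy = np.atleast_2d(np.asarray(data_xy, dtype=float))
    values = np.asarray(values, dtype=float)
    data_xy, values = _dedup(data_xy, values)
    dist = cdist(targets_xy, data_xy)
    cov_all = model(dist)
    sill = model.c
    d_data = None
    rows = []
    for i in range(len(targets_xy)):
        di = dist[i]

        def cov_matrix_of(idx):
            nonlocal d_data
            if d_data is None:
                d_data = cdist(data_xy, data_xy)
            return model(d_data[np.ix_(idx, idx)])

        est = _select_and_solve(
            cov_all[i],
            lambda f, di=di: di <= config.spatial_search_radius_m * f,
            cov_matrix_of,
            values,
            sill,
            config,
        )
        rows.append((est.value, est.variance, est.n_neighbors_used))
    return pd.DataFrame(rows, columns=["estimate", "variance", "n_neighbors"])


def stok_krige(
    targets_st: np.ndarray,
    data_st: np.ndarray,
    values: np.ndarray,
    model: SeparableCovModel,
    config: KrigingConfig = KrigingConfig(),
) -> pd.DataFrame:
    """Spatiotemporal ordinary kriging with a separable covariance.

    Points are ``(x_m, y_m, year)`` triples; the covariance between two
    points is the separable model at their spatial distance and absolute
    year offset.  Neighbor search is restricted to the spatial and
    temporal radii, then ranked by covariance.
    """
    targets_st = np.atleast_2d(np.asarray(targets_st, dtype=float))
    data_st = np.atleast_2d(np.asarray(data_st, dtype=float))
    values = np.asarray(values, dtype=float)
    data_st, values = _dedup(data_st, values)
    sdist = cdist(targets_st[:, :2], data_st[:, :2])
    tdist = np.abs(targets_st[:, 2:3] - data_st[None, :, 2].reshape(1, -1))
    cov_all = model(sdist, tdist)
    sill = model.c0
    sd_data = td_data = None
    rows = []
    for i in range(len(targets_st)):
        sdi, tdi = sdist[i], tdist[i]

        def cov_matrix_of(idx):
            nonlocal sd_data, td_data
            if sd_data is None:
                sd_data = cdist(data_st[:, :2], data_st[:, :2])
                td_data = np.abs(data_st[:, 2][:, None] - data_st[:, 2][None, :])
            return model(sd_data[np.ix_(idx, idx)], td_data[np.ix_(idx, idx)])

        est = _select_and_solve(
            cov_all[i],
            lambda f, sdi=sdi, tdi=tdi: (
                (sdi <= config.spatial_search_radius_m * f)
                & (tdi <= config.temporal_search_radius_yr * f)
            ),
            cov_matrix_of,
            values,
            sill,
            config,
        )
        rows.append((est.value, est.variance, est.n_neighbors_used))
    return pd.DataFrame(rows, columns=["estimate", "variance", "n_neighbors"])
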