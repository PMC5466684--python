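"""Preprocessing: indirect age standardization, log(x+1) transform, detrending.

Incidence tables are pandas DataFrames with (at least) the columns
``town_id, x_m, y_m, year, incidence_per_1e5``; preprocessing adds the
derived columns ``log_value``, ``trend`` and ``residual`` (all in log
units, with ``residual + trend == log_value`` exactly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "StandardizationInputs",
    "indirect_standardize",
    "log_transform",
    "inverse_log_transform",
    "window_trend",
    "detrend",
]


@dataclass
class StandardizationInputs:
    """Inputs of the indirect standardization for one location.

    ``population_by_stratum`` and ``reference_rates`` must cover exactly
    the same strata; all rates are per 100,000.
    """

    population_by_stratum: Mapping[str, float]
    reference_rates: Mapping[str, float]
    reference_overall_rate: float

    def __post_init__(self) -> None:
        if len(self.population_by_stratum) < 1:
            raise ValueError("at least one age stratum is required")
        if set(self.population_by_stratum) != set(self.reference_rates):
            raise ValueError(
                "strata of population table and reference rates must match exactly"
            )
        if any(r < 0 for r in self.reference_rates.values()):
            raise ValueError("reference rates must be >= 0")
        if self.reference_overall_rate < 0:
            raise ValueError("reference overall rate must be >= 0")


def indirect_standardize(observed_cases: float, inputs: StandardizationInputs) -> float:
    """Indirectly age-standardized rate per 100,000.

    Expected cases ``E = sum_a pop_a * ref_rate_a / 1e5``; the
    standardized rate is the standardized incidence ratio
    ``observed / E`` times the reference overall rate.
    """
    if observed_cases < 0:
        raise ValueError("observed case count must be >= 0")
    expected = sum(
        inputs.population_by_stratum[a] * inputs.reference_rates[a] / 1e5
        for a in inputs.population_by_stratum
    )
    if expected <= 0:
        if observed_cases > 0:
            raise ValueError(
                "expected cases are 0 under the reference rates but observed > 0: "
                "no reference support for standardization"
            )
        warnings.warn("expected cases are 0; returning a standardized rate of 0")
        return 0.0
    sir = observed_cases / expected
    return sir * inputs.reference_overall_rate


def log_transform(incidence):
    """``ln(incidence + 1)``; requires incidence >= 0."""
    x = np.asarray(incidence, dtype=float)
    if np.any(x < 0):
        raise ValueError("incidence must be >= 0")
    out = np.log1p(x)
    return out if out.ndim else float(out)


def inverse_log_transform(log_value):
    """``exp(y) - 1``, clamped at 0 so negative log-estimates map to zero incidence."""
    y = np.asarray(log_value, dtype=float)
    out = np.maximum(np.expm1(y), 0.0)
    return out if out.ndim else float(out)


def window_trend(
    query_xy: np.ndarray,
    ref_xy: np.ndarray,
    ref_values: np.ndarray,
    spatial_radius: float,
    *,
    query_t: Optional[np.ndarray] = None,
    ref_t: Optional[np.ndarray] = None,
    temporal_radius: Optional[float] = None,
) -> np.ndarray:
    """Moving-window mean of ``ref_values`` around each query point.

    A reference record contributes when its Euclidean planar distance is
    <= ``spatial_radius`` and (if temporal windows are enabled) its
    absolute year offset is <= ``temporal_radius``, both inclusive.
    Queries with an empty window fall back to the global reference mean.
    """
    query_xy = np.atleast_2d(np.asarray(query_xy, dtype=float))
    ref_xy = np.atleast_2d(np.asarray(ref_xy, dtype=float))
    ref_values = np.asarray(ref_values, dtype=float)
    mask = cdist(query_xy, ref_xy) <= spatial_radius
    if temporal_radius is not None:
        if query_t is None or ref_t is None:
            raise ValueError("temporal windows need query_t and ref_t")
        qt = np.asarray(query_t, dtype=float).reshape(-1, 1)
        rt = np.asarray(ref_t, dtype=float).reshape(1, -1)
        mask &= np.abs(qt - rt) <= temporal_radius
    counts = mask.sum(axis=1)
    sums = mask @ ref_values
    out = np.where(counts > 0, sums / np.maximum(counts, 1), ref_values.mean())
    return out


def detrend(
    df: pd.DataFrame,
    spatial_radius: float,
    temporal_radius: Optional[float] = None,
) -> pd.DataFrame:
    """Populate ``log_value``, ``trend`` and ``residual`` on an incidence table.

    The trend at a record is the unweighted mean of ``log_value`` over
    every record (the record itself included) within the spatial radius
    and, when ``temporal_radius`` is given, within the temporal radius.
    Pass ``temporal_radius=None`` for the projected (purely spatial)
    case.  Returns a copy; ``residual + trend`` reconstructs
    ``log_value`` exactly.
    """
    out = df.copy()
    if "log_value" not in out.columns:
        out["log_value"] = log_transform(out["incidence_per_1e5"].to_numpy())
    xy = out[["x_m", "y_m"]].to_numpy()
    vals = out["log_value"].to_numpy()
    if temporal_radius is None:
        trend = window_trend(xy, xy, vals, spatial_radius)
    else:
        t = out["year"].to_numpy()
        trend = window_trend(
            xy, xy, vals, spatial_radius,
            query_t=t, ref_t=t, temporal_radius=temporal_radius,
        )
    out["trend"] = trend
    out["residual"] = out["log_value"] - out["trend"]
    return out
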