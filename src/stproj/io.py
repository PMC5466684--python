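"""CSV readers/writers for the incidence, population and reference-rate tables.

All tables are comma-separated UTF-8 with a mandatory header row and '.'
decimals.  Coordinates are planar metres, years are integer labels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "INCIDENCE_COLUMNS",
    "read_incidence_csv",
    "write_incidence_csv",
    "read_population_csv",
    "read_reference_rates_csv",
]

INCIDENCE_COLUMNS = ("town_id", "x_m", "y_m", "year", "incidence_per_1e5")
_NUMERIC = ("x_m", "y_m", "year", "incidence_per_1e5")


def read_incidence_csv(path) -> pd.DataFrame:
    """Read and validate an incidence table.

    Requires the columns ``town_id, x_m, y_m, year, incidence_per_1e5``;
    rejects non-numeric cells, negative incidence, and duplicated
    ``(town_id, year)`` pairs, naming the offending row.
    """
    df = pd.read_csv(path, dtype={"town_id": str})
    missing = [c for c in INCIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()] if df[col].notna().any() else []
        bad = df.index[coerced.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric value in column {col!r} at row {int(bad[0])}"
            )
        df[col] = coerced
    neg = df.index[df["incidence_per_1e5"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative incidence at row {int(neg[0])}")
    dup = df.duplicated(subset=["town_id", "year"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(
            f"{path}: duplicate (town_id, year) = "
            f"({df.at[row, 'town_id']}, {int(df.at[row, 'year'])}) at row {row}"
        )
    df["year"] = df["year"].astype(int)
    return df


def write_incidence_csv(df: pd.DataFrame, path) -> None:
    """Write the standard incidence schema (extra columns are preserved)."""
    cols = [c for c in INCIDENCE_COLUMNS if c in df.columns]
    missing = [c for c in INCIDENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cannot write incidence CSV, missing column(s) {missing}")
    extra = [c for c in df.columns if c not in cols]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df[cols + extra].to_csv(path, index=False)


def read_population_csv(path) -> pd.DataFrame:
    """Per-town population by age stratum: town_id index, one column per stratum."""
    df = pd.read_csv(path, dtype={"town_id": str})
    if "town_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'town_id'")
    df = df.set_index("town_id")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or (arr < 0).any():
        raise ValueError(f"{path}: populations must be nonnegative numbers")
    return df


def read_reference_rates_csv(path) -> tuple[dict, float]:
    """Reference age-specific rates per 100,000.

    Expects columns ``stratum, rate_per_1e5``; the row with stratum
    ``overall`` supplies the reference overall rate.
    """
    df = pd.read_csv(path, dtype={"stratum": str})
    for col in ("stratum", "rate_per_1e5"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    rates = dict(zip(df["stratum"], df["rate_per_1e5"].astype(float)))
    if "overall" not in rates:
        raise ValueError(f"{path}: needs an 'overall' stratum row for the overall rate")
    overall = rates.pop("overall")
    if overall < 0 or any(r < 0 for r in rates.values()):
        raise ValueError(f"{path}: rates must be >= 0")
    return rates, overall
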