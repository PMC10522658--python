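"""Population-weighted ZIP-level exposure series from gridded daily weather.

Gridded reanalysis products report daily mean temperature (degC), specific
humidity (kg/kg) and surface pressure (hPa) per grid cell.  Health records
are geocoded to ZIP-level units, so cell values are aggregated with a
precomputed cell -> unit population-weight crosswalk (weights sum to 1 per
unit).  Relative humidity is derived per cell *before* aggregation — RH is
non-linear in its inputs — from vapor pressure

    e = q p / (0.622 + 0.378 q)

and the Magnus saturation vapor pressure

    e_s(T) = 6.112 exp(17.67 T / (T + 243.5))   [hPa]

giving RH = 100 e / e_s, clipped to [0, 100].
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["compute_relative_humidity", "population_weight_to_units",
           "build_exposure_table", "validate_weights"]

_EPSILON = 0.622  # ratio of molar masses, water vapor to dry air


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        bad = np.flatnonzero(~np.isfinite(arr))
        raise ValueError(f"non-finite {name} at positions {bad[:5].tolist()}")


def compute_relative_humidity(temperature, specific_humidity, pressure):
    """Relative humidity (%) from T (degC), q (kg/kg) and p (hPa).

    Vectorized; result clipped to [0, 100].  Saturated air (e = e_s) gives
    100, dry air (q = 0) gives 0.
    """
    t = np.asarray(temperature, dtype=float)
    q = np.asarray(specific_humidity, dtype=float)
    p = np.asarray(pressure, dtype=float)
    for name, arr in (("temperature", t), ("specific_humidity", q),
                      ("pressure", p)):
        _check_finite(name, np.atleast_1d(arr))
    if np.any(np.atleast_1d(q) < 0):
        raise ValueError("specific_humidity must be >= 0")
    if np.any(np.atleast_1d(p) <= 0):
        raise ValueError("pressure must be > 0")
    e = q * p / (_EPSILON + (1.0 - _EPSILON) * q)
    e_s = 6.112 * np.exp(17.67 * t / (t + 243.5))
    rh = np.clip(100.0 * e / e_s, 0.0, 100.0)
    return rh if rh.ndim else float(rh)


def validate_weights(weights: pd.DataFrame, tol: float = 1e-9) -> None:
    """Check crosswalk invariants: weights >= 0, summing to 1 per unit."""
    if (weights["weight"] < 0).any():
        raise ValueError("negative crosswalk weights")
    sums = weights.groupby("unit_id")["weight"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(
            f"crosswalk weights do not sum to 1 for units {bad.index.tolist()[:5]}"
        )


def population_weight_to_units(grid_values, weights: pd.DataFrame) -> pd.Series:
    """Population-weighted unit values for one day of cell values.

    ``grid_values`` maps cell_id -> value (Series or dict); the result is a
    convex combination per unit, so it lies within the range of the
    contributing cell values.
    """
    vals = pd.Series(grid_values)
    missing = set(weights["cell_id"]) - set(vals.index)
    if missing:
        raise ValueError(f"cells referenced by weights missing from grid: "
                         f"{sorted(missing)!r}")
    w = weights.copy()
    w["value"] = vals.reindex(w["cell_id"]).to_numpy()
    return w.groupby("unit_id").apply(
        lambda g: float(np.dot(g["weight"], g["value"])), include_groups=False)


def build_exposure_table(grid: pd.DataFrame, weights: pd.DataFrame,
                         period: tuple | None = None) -> pd.DataFrame:
    """Daily unit-level temperature and relative humidity.

    ``grid`` is long-format (cell_id, date, temperature, specific_humidity,
    pressure) with a contiguous calendar per cell over ``period`` (default:
    the grid's full span).  RH is computed per cell, then both variables are
    population-weighted with the crosswalk.  Output has exactly one row per
    (unit, day).
    """
    validate_weights(weights)
    g = grid.copy()
    g["date"] = pd.to_datetime(g["date"])
    if period is not None:
        start, end = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        g = g[(g["date"] >= start) & (g["date"] <= end)]
    else:
        start, end = g["date"].min(), g["date"].max()
    all_days = pd.date_range(start, end, freq="D")

    cells = weights["cell_id"].unique()
    present = set(g["cell_id"].unique())
    missing_cells = [c for c in cells if c not in present]
    if missing_cells:
        raise ValueError(f"grid lacks cells {missing_cells!r}")

    g = g[g["cell_id"].isin(cells)]
    g["relative_humidity"] = compute_relative_humidity(
        g["temperature"], g["specific_humidity"], g["pressure"])

    t_wide = g.pivot_table(index="cell_id", columns="date",
                           values="temperature", aggfunc="first")
    r_wide = g.pivot_table(index="cell_id", columns="date",
                           values="relative_humidity", aggfunc="first")
    t_wide = t_wide.reindex(index=cells, columns=all_days)
    r_wide = r_wide.reindex(index=cells, columns=all_days)
    if t_wide.isna().any().any():
        cell = t_wide.index[t_wide.isna().any(axis=1)][0]
        day = t_wide.columns[t_wide.loc[cell].isna()][0]
        raise ValueError(f"grid calendar gap: cell {cell!r} missing {day.date()}")

    units = weights["unit_id"].unique()
    w_mat = (weights.pivot_table(index="unit_id", columns="cell_id",
                                 values="weight", aggfunc="sum", fill_value=0.0)
             .reindex(index=units, columns=cells, fill_value=0.0))
    t_unit = w_mat.to_numpy() @ t_wide.to_numpy()
    r_unit = w_mat.to_numpy() @ r_wide.to_numpy()

    n_u, n_d = len(units), len(all_days)
    return pd.DataFrame({
        "unit_id": np.repeat(units, n_d),
        "date": np.tile(all_days.values, n_u),
        "temperature": t_unit.ravel(),
        "relative_humidity": r_unit.ravel(),
    })
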