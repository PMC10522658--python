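"""Reported effect quantities and the end-to-end analysis driver.

Fitted cross-basis coefficients are turned into the quantities an
epidemiologist reports: the cumulative percent change in visit rates at a
temperature relative to the reference (the period-minimum temperature by
default), with delta-method 95% confidence intervals; full exposure-response
curves over the observed temperature range; contrasts at named temperature
percentiles; stratified runs by location, sex, age group and vulnerability
tertile; a short-lag (0-1 day) secondary model; and the
with-versus-without-humidity sensitivity comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .clr import FitResult, aic_grid_select, fit_strata
from .crossover import StrataSet, build_strata
from .dlnm import CrossBasisSpec, cumulative_contrast

logger = logging.getLogger(__name__)

__all__ = [
    "percent_change", "celsius_to_fahrenheit", "temperature_percentiles",
    "curve_table", "CurveTable", "run_analysis", "sensitivity_compare",
    "AnalysisConfig",
]

Z95 = 1.959963985  # standard-normal 97.5% quantile


def percent_change(eta: float, var: float, level: float = 0.95
                   ) -> tuple[float, float, float]:
    """Percent change and CI for a log-rate-ratio with delta-method variance.

    Point = ``100 (exp(eta) - 1)``; CI endpoints from ``eta +- z sqrt(var)``.
    """
    if var < 0:
        raise ValueError("variance must be >= 0")
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    se = np.sqrt(var)
    pt = 100.0 * (np.exp(eta) - 1.0)
    lo = 100.0 * (np.exp(eta - z * se) - 1.0)
    hi = 100.0 * (np.exp(eta + z * se) - 1.0)
    return float(pt), float(lo), float(hi)


def celsius_to_fahrenheit(c, ndigits: int | None = 1):
    """degC -> degF, reported to 1 decimal by convention."""
    f = np.asarray(c, dtype=float) * 9.0 / 5.0 + 32.0
    if ndigits is not None:
        f = np.round(f, ndigits)
    return float(f) if f.ndim == 0 else f


def temperature_percentiles(values, probs=(50, 75, 90, 99)) -> pd.DataFrame:
    """Empirical percentiles (linear interpolation) in degC with degF."""
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no finite temperature values")
    cs = np.percentile(v, probs)
    return pd.DataFrame({"percentile": list(probs), "celsius": cs,
                         "fahrenheit": celsius_to_fahrenheit(cs)})


@dataclass
class CurveTable:
    """Exposure-response curve plus named percentile contrasts.

    ``curve`` has one row per grid temperature; ``percentile_contrasts`` one
    row per requested percentile.  The estimate at the reference temperature
    is exactly (0, 0, 0).
    """

    cause: str
    stratum_label: str
    reference_temperature: float
    lag_window: str
    curve: pd.DataFrame
    percentile_contrasts: pd.DataFrame
    n_strata: int = 0


def _contrast_rows(fit: FitResult, spec: CrossBasisSpec, temps,
                   lag_subset=None) -> pd.DataFrame:
    k = spec.n_columns
    theta = fit.coefficients[:k]
    cov = fit.covariance[:k, :k]
    rows = []
    for t in np.atleast_1d(temps):
        eta, var = cumulative_contrast(theta, cov, spec, float(t), lag_subset)
        pt, lo, hi = percent_change(eta, var)
        rows.append({"at_temperature": float(t), "log_rr": eta,
                     "variance": var, "percent_change": pt,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def curve_table(fit: FitResult, spec: CrossBasisSpec, exposure_values,
                cause: str = "", stratum_label: str = "overall",
                grid_n: int = 100, percentiles=(50, 75, 90, 99),
                lag_subset=None) -> CurveTable:
    """Cumulative percent-change curve over the observed temperature range.

    The grid is ``grid_n`` equally spaced points between the observed min and
    max of ``exposure_values``; percentile contrasts are evaluated at the
    empirical percentiles of the same distribution.
    """
    v = np.asarray(exposure_values, dtype=float).ravel()
    grid = np.linspace(np.nanmin(v), np.nanmax(v), grid_n)
    curve = _contrast_rows(fit, spec, grid, lag_subset)
    pct_temps = temperature_percentiles(v, percentiles)
    pc = _contrast_rows(fit, spec, pct_temps["celsius"].to_numpy(), lag_subset)
    pc.insert(0, "percentile", list(percentiles))
    lag_label = ("0-%d" % spec.max_lag if lag_subset is None
                 else ",".join(str(l) for l in sorted(lag_subset)))
    return CurveTable(cause=cause, stratum_label=stratum_label,
                      reference_temperature=spec.reference_value,
                      lag_window=lag_label, curve=curve,
                      percentile_contrasts=pc)


@dataclass
class AnalysisConfig:
    """Settings for one end-to-end run.

    ``df_var``/``df_lag`` fix the spline dimensions; leaving both ``None``
    selects them by AIC over ``var_df_grid x lag_df_grid`` on the overall
    fit per cause.  ``reference_temperature=None`` uses the observed minimum
    of the exposure series.  ``percentile_source`` chooses the distribution
    percentiles are computed over: pooled case+control lagged exposures
    (default) or case-day exposures.
    """

    causes: tuple[str, ...] = ("alcohol_related", "substance_related")
    max_lag: int = 6
    df_var: int | None = None
    df_lag: int | None = None
    var_df_grid: tuple[int, ...] = (3, 4)
    lag_df_grid: tuple[int, ...] = (2, 3, 4, 5)
    reference_temperature: float | None = None
    percentiles: tuple[float, ...] = (50, 75, 90, 99)
    percentile_source: str = "case_control"  # or "case_days"
    include_rh: bool = True
    stratify: bool = True
    secondary_lag01: bool = True
    grid_n: int = 100


def _fit_and_curve(strata: StrataSet, cfg: AnalysisConfig, var_df: int,
                   lag_df: int | None, cause: str, label: str,
                   max_lag: int | None = None) -> tuple[FitResult, CurveTable]:
    max_lag = strata.max_lag if max_lag is None else max_lag
    lag_t = strata.lag_temperature[:, :max_lag + 1]
    lag_r = strata.lag_rh[:, :max_lag + 1]
    sub = StrataSet(events=strata.events, row_stratum=strata.row_stratum,
                    row_date=strata.row_date, row_is_case=strata.row_is_case,
                    lag_temperature=lag_t, lag_rh=lag_r, max_lag=max_lag)
    t_spec = CrossBasisSpec.from_exposure(lag_t, var_df, max_lag, lag_df,
                                          cfg.reference_temperature)
    rh_spec = (CrossBasisSpec.from_exposure(lag_r, var_df, max_lag, lag_df)
               if cfg.include_rh else None)
    fit = fit_strata(sub, t_spec, rh_spec)
    if cfg.percentile_source == "case_days":
        vals = lag_t[sub.row_is_case.astype(bool), 0]
    else:
        vals = lag_t
    curve = curve_table(fit, t_spec, vals, cause=cause, stratum_label=label,
                        grid_n=cfg.grid_n, percentiles=cfg.percentiles)
    curve.n_strata = sub.n_strata
    return fit, curve


def run_analysis(events_by_cause: dict[str, pd.DataFrame],
                 exposure: pd.DataFrame,
                 config: AnalysisConfig | None = None) -> dict:
    """Full pipeline from case events to effect tables, per cause.

    For each cause: build time-stratified strata, select or fix spline
    degrees of freedom, fit the conditional-logistic DLNM, and emit the
    overall curve table, stratified curve tables (location, sex, age group,
    SVI tertile) reusing the selected dfs, and the 0-1-day secondary model
    (a refit at ``max_lag=1`` with an unconstrained lag basis).
    """
    cfg = config or AnalysisConfig()
    out: dict = {}
    for cause in cfg.causes:
        events = events_by_cause.get(cause)
        if events is None or len(events) == 0:
            logger.warning("no events for cause %r; skipped", cause)
            continue
        try:
            strata = build_strata(events, exposure, max_lag=cfg.max_lag)
        except ValueError as err:
            raise RuntimeError(f"[build_strata] cause {cause!r}: {err}") from err

        if cfg.df_var is not None and cfg.df_lag is not None:
            var_df, lag_df, aic_table = cfg.df_var, cfg.df_lag, None
            df_source = "fixed"
        else:
            var_df, lag_df, aic_table = aic_grid_select(
                strata, cfg.var_df_grid, cfg.lag_df_grid, cfg.max_lag,
                include_rh=cfg.include_rh,
                reference_value=cfg.reference_temperature)
            df_source = "aic"

        fit, curve = _fit_and_curve(strata, cfg, var_df, lag_df, cause,
                                    "overall")
        result = {"n_strata": strata.n_strata, "df_var": var_df,
                  "df_lag": lag_df, "df_source": df_source,
                  "aic_table": aic_table, "fit": fit,
                  "curves": {"overall": curve}}

        if cfg.stratify:
            ev = strata.events
            groupings = {
                "location": ev.get("location_group"),
                "sex": ev.get("sex"),
                "age_group": ev.get("age_group"),
                "svi_tertile": ev.get("svi_tertile"),
            }
            for gname, col in groupings.items():
                if col is None:
                    continue
                for level in pd.unique(col):
                    mask = (col == level).to_numpy()
                    if mask.sum() == 0:
                        logger.warning("empty stratum %s=%s for %s; skipped",
                                       gname, level, cause)
                        continue
                    label = f"{gname}={level}"
                    try:
                        _, c = _fit_and_curve(strata.subset(mask), cfg,
                                              var_df, lag_df, cause, label)
                        result["curves"][label] = c
                    except (ValueError, RuntimeError) as err:
                        logger.warning("stratum %s for %s failed: %s",
                                       label, cause, err)

        if cfg.secondary_lag01:
            _, c01 = _fit_and_curve(strata, cfg, var_df, None, cause,
                                    "overall", max_lag=1)
            c01.lag_window = "0-1"
            result["curves_lag01"] = {"overall": c01}
            # lag-subset contrast from the 0-6 fit is also available
            t_spec = CrossBasisSpec.from_exposure(
                strata.lag_temperature, var_df, cfg.max_lag, lag_df,
                cfg.reference_temperature)
            result["lag01_subset_curve"] = curve_table(
                fit, t_spec, strata.lag_temperature, cause=cause,
                stratum_label="overall", grid_n=cfg.grid_n,
                percentiles=cfg.percentiles, lag_subset={0, 1})
        out[cause] = result
        logger.info("cause %s: %d strata, df=(%d,%d) [%s]", cause,
                    strata.n_strata, var_df, lag_df, df_source)
    return out


def sensitivity_compare(estimates_main, estimates_alt
                        ) -> tuple[float, float, tuple[float, float]]:
    """Agreement between matched effect-estimate sets (e.g. with vs without
    humidity adjustment): Pearson R, least-squares slope of alt on main, and
    the slope's normal-theory 95% CI."""
    a = np.asarray(estimates_main, dtype=float).ravel()
    b = np.asarray(estimates_alt, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 3:
        raise ValueError("need at least 3 matched estimates")
    res = stats.linregress(a, b)
    half = Z95 * res.stderr if np.isfinite(res.stderr) else 0.0
    return float(res.rvalue), float(res.slope), (float(res.slope - half),
                                                 float(res.slope + half))
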