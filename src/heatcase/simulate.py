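"""Synthetic stand-ins for the restricted pipeline inputs.

The real inputs — statewide hospital discharge records, gridded reanalysis
weather, census crosswalks and social-vulnerability scores — are access
restricted or large.  This module generates structurally faithful synthetic
versions with a *known* exposure-lag-response surface, so every pipeline
stage and the full parameter-recovery loop can be exercised at desk scale.

Weather per grid cell is a seasonal sinusoid plus an AR(1) process; humidity
and pressure are generated jointly so downstream relative humidity lies
inside (5, 100).  Case events arise as daily Poisson counts per unit whose
log-mean is a baseline plus the summed surface contributions of lagged
temperature, exactly the structure the conditional-logistic DLNM assumes.
All randomness flows from one explicitly passed seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .weather import compute_relative_humidity

__all__ = [
    "Surface", "NullSurface", "LinearSurface", "ThresholdSurface",
    "surface_from_dict", "WeatherParams", "SimulationTruth",
    "simulate_weather", "simulate_admissions", "write_fixture_bundle",
    "DEFAULT_CAUSE_MAP",
]

# example clinical-classification style cause map (illustrative, not a
# certified crosswalk): 3-4 digit patterns match as prefixes
DEFAULT_CAUSE_MAP: dict[str, list[str]] = {
    "alcohol_related": ["291", "303", "3050"],
    "substance_related": ["292", "304", "3052", "3053", "3054", "3055",
                          "3056", "3057", "3058", "3059"],
    "cannabis": ["3043", "3052"],
    "cocaine": ["3042", "3056"],
    "opioids": ["3040", "3047", "3055"],
    "sedatives": ["3041", "3054"],
}

_FILLER_DX = ["4019", "25000", "41401", "486", "5990", "2724", "311", "78650"]


class Surface:
    """Exposure-lag-response surface: log-rate contribution of temperature
    ``t`` at lag ``l``.  Must vanish at the reference temperature for every
    lag (identifiability)."""

    reference: float

    def __call__(self, t, lag):  # pragma: no cover - interface
        raise NotImplementedError

    def cumulative(self, t, max_lag: int = 6) -> float:
        """Sum of contributions over lags 0..max_lag at temperature ``t``."""
        return float(sum(np.asarray(self(t, l), float) for l in range(max_lag + 1)))

    def to_dict(self) -> dict:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class NullSurface(Surface):
    """No temperature effect; used for CI calibration checks."""

    reference: float = 0.0

    def __call__(self, t, lag):
        return np.zeros_like(np.asarray(t, dtype=float))

    def to_dict(self) -> dict:
        return {"family": "null", "reference": self.reference}


@dataclass(frozen=True)
class LinearSurface(Surface):
    """Linear in temperature, constant across lags.

    ``slope_per_degc`` is the *cumulative* (summed over lags 0..max_lag)
    log-rate-ratio per +1 degC, so each lag contributes
    ``slope_per_degc / (max_lag + 1)`` per degC above the reference.
    """

    slope_per_degc: float
    reference: float
    max_lag: int = 6

    def __call__(self, t, lag):
        per_lag = self.slope_per_degc / (self.max_lag + 1)
        return per_lag * (np.asarray(t, dtype=float) - self.reference)

    def to_dict(self) -> dict:
        return {"family": "linear", "slope_per_degc": self.slope_per_degc,
                "reference": self.reference, "max_lag": self.max_lag}


@dataclass(frozen=True)
class ThresholdSurface(Surface):
    """Linear up to a threshold temperature, flat above it."""

    slope_per_degc: float
    reference: float
    threshold: float
    max_lag: int = 6

    def __call__(self, t, lag):
        per_lag = self.slope_per_degc / (self.max_lag + 1)
        t = np.minimum(np.asarray(t, dtype=float), self.threshold)
        return per_lag * (t - min(self.reference, self.threshold))

    def to_dict(self) -> dict:
        return {"family": "threshold", "slope_per_degc": self.slope_per_degc,
                "reference": self.reference, "threshold": self.threshold,
                "max_lag": self.max_lag}


def surface_from_dict(d: dict) -> Surface:
    fam = d["family"]
    kw = {k: v for k, v in d.items() if k != "family"}
    return {"null": NullSurface, "linear": LinearSurface,
            "threshold": ThresholdSurface}[fam](**kw)


@dataclass(frozen=True)
class WeatherParams:
    """Seasonal-AR(1) daily temperature model per grid cell.

    ``mean`` (degC) and ``amplitude`` (degC) set the annual cycle,
    ``ar1`` in (-1, 1) the day-to-day persistence of the anomaly,
    ``noise_sd`` (degC) the AR(1) innovation standard deviation,
    ``cell_offset_sd`` the spread of time-constant cell offsets.
    """

    mean: float = 10.0
    amplitude: float = 12.0
    ar1: float = 0.7
    noise_sd: float = 2.5
    cell_offset_sd: float = 1.0
    phase_days: float = 105.0  # annual minimum near early February

    def __post_init__(self):
        if not -1 < self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in (-1, 1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Complete data-generating configuration for one synthetic study."""

    surface: Surface = field(default_factory=NullSurface)
    baseline_log_rate: float = -4.0   # log expected cases per unit-day
    weather: WeatherParams = field(default_factory=WeatherParams)
    n_units: int = 30
    n_cells: int = 12
    period: tuple[str, str] = ("2001-01-01", "2004-12-31")
    seed: int = 0
    female_fraction: float = 0.42
    inpatient_fraction: float = 0.75
    age_group_probs: tuple[float, ...] = (0.13, 0.50, 0.32, 0.05)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def simulate_weather(truth: SimulationTruth,
                     rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Synthetic gridded daily weather (long format).

    Temperature per cell: seasonal sinusoid + time-constant cell offset +
    AR(1) anomaly.  Specific humidity is back-computed from a smoothly
    varying target relative humidity in (10, 95), so the RH recovered
    downstream stays inside (5, 100).
    """
    rng = truth.rng() if rng is None else rng
    start = pd.Timestamp(truth.period[0])
    end = pd.Timestamp(truth.period[1])
    days = pd.date_range(start, end, freq="D")
    n_d = len(days)
    doy = np.arange(n_d, dtype=float)
    wp = truth.weather
    season = wp.mean + wp.amplitude * np.sin(
        2 * np.pi * (doy - wp.phase_days) / 365.25)

    frames = []
    for c in range(truth.n_cells):
        offset = rng.normal(0.0, wp.cell_offset_sd)
        innov = rng.normal(0.0, wp.noise_sd, n_d)
        anom = np.empty(n_d)
        denom = np.sqrt(max(1.0 - wp.ar1 ** 2, 1e-12))
        anom[0] = innov[0] / denom
        for i in range(1, n_d):
            anom[i] = wp.ar1 * anom[i - 1] + innov[i]
        temp = season + offset + anom

        # smooth RH target in (10, 95), then invert q from RH, T, p
        rh_anom = np.empty(n_d)
        rh_innov = rng.normal(0.0, 6.0, n_d)
        rh_anom[0] = rh_innov[0] / denom
        for i in range(1, n_d):
            rh_anom[i] = wp.ar1 * rh_anom[i - 1] + rh_innov[i]
        rh = np.clip(65.0 + rh_anom, 10.0, 95.0)
        pressure = 1013.0 + rng.normal(0.0, 4.0, n_d)
        e_s = 6.112 * np.exp(17.67 * temp / (temp + 243.5))
        e = rh / 100.0 * e_s
        q = 0.622 * e / (pressure - 0.378 * e)

        frames.append(pd.DataFrame({
            "cell_id": f"cell{c:03d}", "date": days, "temperature": temp,
            "specific_humidity": q, "pressure": pressure}))
    return pd.concat(frames, ignore_index=True)


def _linear_predictor(truth: SimulationTruth, temp: np.ndarray,
                      max_lag: int) -> np.ndarray:
    """Summed surface contributions of lags 0..max_lag per day (first
    ``max_lag`` days are NaN: no full history)."""
    n = temp.size
    lp = np.zeros(n)
    for l in range(max_lag + 1):
        contrib = np.asarray(truth.surface(temp, l), dtype=float)
        lp[max_lag:] += contrib[max_lag - l: n - l]
    lp[:max_lag] = np.nan
    return lp


def simulate_admissions(truth: SimulationTruth, exposure: pd.DataFrame,
                        cause_map: dict | None = None,
                        rng: np.random.Generator | None = None,
                        target_cases: int | None = None,
                        max_lag: int = 6,
                        contamination: float = 0.0) -> pd.DataFrame:
    """Synthetic admission records whose daily rates follow the truth surface.

    Daily counts per unit are Poisson with log-mean ``baseline +
    sum_l surface(T_lag_l, l)``; each count expands to one record with
    diagnosis codes drawn to match ``cause_map``, and demographic fields from
    the configured margins.  ``target_cases`` recalibrates the baseline so
    the *expected* total equals it.  ``contamination`` blanks one key field
    in that fraction of records to exercise the exclusion rules.
    """
    rng = truth.rng() if rng is None else rng
    cause_map = DEFAULT_CAUSE_MAP if cause_map is None else cause_map
    exp = exposure.copy()
    exp["date"] = pd.to_datetime(exp["date"])

    lp_frames = []
    for unit, g in exp.groupby("unit_id", sort=False):
        g = g.sort_values("date")
        lp = _linear_predictor(truth, g["temperature"].to_numpy(float), max_lag)
        lp_frames.append(pd.DataFrame({
            "unit_id": unit, "date": g["date"].to_numpy(), "lp": lp}))
    lp_all = pd.concat(lp_frames, ignore_index=True).dropna(subset=["lp"])

    rel = np.exp(lp_all["lp"].to_numpy())
    if target_cases is not None:
        lam = rel * (target_cases / rel.sum())
    else:
        lam = np.exp(truth.baseline_log_rate) * rel
    counts = rng.poisson(lam)

    n_total = int(counts.sum())
    if n_total == 0:
        return pd.DataFrame(columns=["record_id", "admission_date", "unit_id",
                                     "dx1", "dx2", "dx3", "dx4", "age", "sex",
                                     "admission_type"])
    rep = np.repeat(np.arange(len(lp_all)), counts)
    dates = lp_all["date"].to_numpy()[rep]
    units = lp_all["unit_id"].to_numpy()[rep]

    patterns = sorted({p for pats in cause_map.values() for p in pats})
    dx1 = [_concrete_code(rng.choice(patterns), rng) for _ in range(n_total)]
    dx_other = rng.choice(_FILLER_DX, size=(n_total, 3))

    ages = _sample_ages(truth, rng, n_total)
    sex = np.where(rng.random(n_total) < truth.female_fraction,
                   "female", "male")
    adm = np.where(rng.random(n_total) < truth.inpatient_fraction,
                   "inpatient", "outpatient")

    rec = pd.DataFrame({
        "record_id": [f"r{i:07d}" for i in range(n_total)],
        "admission_date": pd.to_datetime(dates).strftime("%Y-%m-%d"),
        "unit_id": units, "dx1": dx1, "dx2": dx_other[:, 0],
        "dx3": dx_other[:, 1], "dx4": dx_other[:, 2],
        "age": ages, "sex": sex, "admission_type": adm,
    })
    if contamination > 0:
        n_bad = int(round(contamination * n_total))
        bad_rows = rng.choice(n_total, size=n_bad, replace=False)
        fields = rng.choice(["sex", "age", "admission_date", "unit_id"],
                            size=n_bad)
        rec = rec.astype({"age": "object"})
        for i, f in zip(bad_rows, fields):
            rec.loc[i, f] = ""
    return rec


def _concrete_code(pattern: str, rng: np.random.Generator) -> str:
    """A concrete 5-character ICD-9-CM code matching a (prefix) pattern."""
    code = pattern
    while len(code) < 5:
        code += str(rng.integers(0, 10))
    return code


def _sample_ages(truth: SimulationTruth, rng: np.random.Generator,
                 n: int) -> np.ndarray:
    bins = [(0, 24), (25, 44), (45, 64), (65, 95)]
    groups = rng.choice(len(bins), size=n, p=truth.age_group_probs)
    lo = np.array([bins[g][0] for g in groups])
    hi = np.array([bins[g][1] for g in groups])
    return rng.integers(lo, hi + 1)


def _population_weights(truth: SimulationTruth,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Each unit weighted over up to 3 random cells, weights Dirichlet."""
    rows = []
    k = min(3, truth.n_cells)
    for u in range(truth.n_units):
        cells = rng.choice(truth.n_cells, size=k, replace=False)
        w = rng.dirichlet(np.ones(k))
        for c, wt in zip(cells, w):
            rows.append({"unit_id": f"z{u:05d}", "cell_id": f"cell{c:03d}",
                         "weight": wt})
    return pd.DataFrame(rows)


def _area_weights_and_svi(truth: SimulationTruth, rng: np.random.Generator
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """2-3 synthetic tracts per unit with Dirichlet area shares; tract SVI
    uniform on [0, 1]."""
    aw_rows, svi_rows = [], []
    t = 0
    for u in range(truth.n_units):
        k = int(rng.integers(2, 4))
        shares = rng.dirichlet(np.ones(k))
        for s in shares:
            tract = f"t{t:06d}"
            aw_rows.append({"tract_id": tract, "unit_id": f"z{u:05d}",
                            "weight": s})
            svi_rows.append({"tract_id": tract,
                             "svi_value": float(rng.uniform())})
            t += 1
    return pd.DataFrame(aw_rows), pd.DataFrame(svi_rows)


def write_fixture_bundle(truth: SimulationTruth, out_dir,
                         cause_map: dict | None = None,
                         contamination: float = 0.02,
                         target_cases: int | None = 4000,
                         overwrite: bool = False) -> dict[str, Path]:
    """Write a complete synthetic input bundle to ``out_dir``.

    Emits admissions, gridded weather, both crosswalks, tract SVI, the city
    unit list, the cause-map config and a truth manifest recording the
    surface family, parameters and seed.
    """
    from .weather import build_exposure_table  # local import, avoids cycle

    out = Path(out_dir)
    manifest = out / "truth.yaml"
    if manifest.exists() and not overwrite:
        raise FileExistsError(f"bundle already exists at {out}; "
                              "pass overwrite=True to replace it")
    out.mkdir(parents=True, exist_ok=True)
    rng = truth.rng()
    cause_map = DEFAULT_CAUSE_MAP if cause_map is None else cause_map

    grid = simulate_weather(truth, rng)
    pop_w = _population_weights(truth, rng)
    area_w, tract_svi = _area_weights_and_svi(truth, rng)
    exposure = build_exposure_table(grid, pop_w)
    admissions = simulate_admissions(truth, exposure, cause_map, rng,
                                     target_cases=target_cases,
                                     contamination=contamination)
    city_units = [f"z{u:05d}" for u in range(max(1, truth.n_units // 3))]

    paths = {}
    for name, df in [("weather_grid", grid), ("population_weights", pop_w),
                     ("area_weights", area_w), ("tract_svi", tract_svi),
                     ("admissions", admissions)]:
        p = out / f"{name}.csv"
        d = df.copy()
        if "date" in d.columns:
            d["date"] = pd.to_datetime(d["date"]).dt.strftime("%Y-%m-%d")
        d.to_csv(p, index=False)
        paths[name] = p

    cfg = {
        "cause_map": {k: list(v) for k, v in cause_map.items()},
        "city_units": city_units,
    }
    p = out / "cause_map.yaml"
    p.write_text(yaml.safe_dump(cfg, sort_keys=False))
    paths["cause_map"] = p

    truth_doc = {
        "surface": truth.surface.to_dict(),
        "baseline_log_rate": truth.baseline_log_rate,
        "weather": {
            "mean": truth.weather.mean, "amplitude": truth.weather.amplitude,
            "ar1": truth.weather.ar1, "noise_sd": truth.weather.noise_sd,
            "cell_offset_sd": truth.weather.cell_offset_sd,
            "phase_days": truth.weather.phase_days,
        },
        "n_units": truth.n_units, "n_cells": truth.n_cells,
        "period": list(truth.period), "seed": truth.seed,
        "target_cases": target_cases, "contamination": contamination,
    }
    manifest.write_text(yaml.safe_dump(truth_doc, sort_keys=False))
    paths["truth"] = manifest
    return paths
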