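"""Delimited-text readers and writers for the pipeline's file formats.

All inputs are plain CSV with ISO-8601 dates; configuration (cause map, city
unit list, analysis settings) is YAML.  Readers validate the schema and the
basic invariants of each table on the way in.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

__all__ = [
    "read_grid_series", "read_exposure", "write_exposure", "read_admissions",
    "read_crosswalk", "read_tract_svi", "read_cause_config", "load_bundle",
]

_GRID_COLS = ["cell_id", "date", "temperature", "specific_humidity", "pressure"]
_EXPOSURE_COLS = ["unit_id", "date", "temperature", "relative_humidity"]
_ADMISSION_COLS = ["record_id", "admission_date", "unit_id", "dx1", "dx2",
                   "dx3", "dx4", "age", "sex", "admission_type"]


def _require(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{what} file lacks columns {missing}")


def read_grid_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, _GRID_COLS, "grid weather")
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(["cell_id", "date"]).any():
        raise ValueError("duplicate (cell_id, date) rows in grid weather")
    if (df["specific_humidity"] < 0).any():
        raise ValueError("negative specific humidity")
    if (df["pressure"] <= 0).any():
        raise ValueError("non-positive pressure")
    return df


def read_exposure(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, _EXPOSURE_COLS, "exposure")
    df["date"] = pd.to_datetime(df["date"])
    if df.duplicated(["unit_id", "date"]).any():
        raise ValueError("duplicate (unit_id, date) rows in exposure")
    rh = df["relative_humidity"]
    if ((rh < 0) | (rh > 100)).any():
        raise ValueError("relative humidity outside [0, 100]")
    return df


def write_exposure(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.strftime("%Y-%m-%d")
    out[_EXPOSURE_COLS].to_csv(path, index=False)


def read_admissions(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"unit_id": "string", "dx1": "string",
                                  "dx2": "string", "dx3": "string",
                                  "dx4": "string"}, keep_default_na=True)
    _require(df, _ADMISSION_COLS, "admissions")
    return df


def read_crosswalk(path, kind: str = "population") -> pd.DataFrame:
    df = pd.read_csv(path)
    key = "cell_id" if kind == "population" else "tract_id"
    _require(df, [key, "unit_id", "weight"], f"{kind} crosswalk")
    if (df["weight"] < 0).any():
        raise ValueError("negative crosswalk weights")
    return df


def read_tract_svi(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["tract_id", "svi_value"], "tract SVI")
    if ((df["svi_value"] < 0) | (df["svi_value"] > 1)).any():
        raise ValueError("SVI values outside [0, 1]")
    return df


def read_cause_config(path) -> tuple[dict[str, list[str]], list[str]]:
    """Cause map and city-unit list from a YAML config."""
    doc = yaml.safe_load(Path(path).read_text())
    cause_map = {str(k): [str(p) for p in v]
                 for k, v in doc["cause_map"].items()}
    city_units = [str(u) for u in doc.get("city_units", [])]
    return cause_map, city_units


def example_cause_config() -> tuple[dict[str, list[str]], list[str]]:
    """The packaged illustrative cause map (six causes)."""
    from importlib import resources

    path = resources.files("heatcase.data") / "cause_map_example.yaml"
    return read_cause_config(path)


def load_bundle(bundle_dir) -> dict:
    """Read a full input bundle (as written by write_fixture_bundle)."""
    d = Path(bundle_dir)
    cause_map, city_units = read_cause_config(d / "cause_map.yaml")
    return {
        "grid": read_grid_series(d / "weather_grid.csv"),
        "population_weights": read_crosswalk(d / "population_weights.csv"),
        "area_weights": read_crosswalk(d / "area_weights.csv", kind="area"),
        "tract_svi": read_tract_svi(d / "tract_svi.csv"),
        "admissions": read_admissions(d / "admissions.csv"),
        "cause_map": cause_map,
        "city_units": city_units,
    }
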