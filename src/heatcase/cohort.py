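"""Cohort construction: cause classification, exclusions, stratification.

Admissions carry up to four ICD-9-CM diagnosis codes; an admission counts as
a case of a cause when at least one of those four positions matches the
cause's code set, so one admission can contribute to several causes.  Code
patterns follow clinical-classification semantics at mixed granularity:
a 3- or 4-digit pattern (dots ignored) matches as a prefix, a 5-digit
pattern exactly.

Records with missing or unparseable sex, age, admission date or residential
ZIP are excluded, with per-table counts and the percentage excluded.  Units
receive an area-weighted social-vulnerability (SVI) score in [0, 1] and are
split into tertiles (1 = least vulnerable) of as-equal-as-possible size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalize_icd", "classify_admission", "classify_admissions",
    "apply_exclusions", "exclusion_percent", "assign_svi_tertiles",
    "extract_case_series", "AGE_BINS", "AGE_LABELS", "ExclusionReport",
]

DX_COLUMNS = ["dx1", "dx2", "dx3", "dx4"]
AGE_BINS = [0, 25, 45, 65, np.inf]
AGE_LABELS = ["0-24", "25-44", "45-64", "65+"]
SEXES = {"female", "male"}


def normalize_icd(code: str) -> str:
    """Canonical ICD-9-CM form: uppercase, dot removed (304.3 -> 3043)."""
    return str(code).strip().upper().replace(".", "")


def _matches(code: str, patterns: list[str]) -> bool:
    c = normalize_icd(code)
    if not c:
        return False
    for p in patterns:
        if len(p) >= 5:
            if c == p:
                return True
        elif c.startswith(p):
            return True
    return False


def _normalize_cause_map(cause_map: dict) -> dict[str, list[str]]:
    out = {}
    for cause, patterns in cause_map.items():
        pats = sorted({normalize_icd(p) for p in patterns})
        if not pats or any(not p for p in pats):
            raise ValueError(f"cause {cause!r} has an empty pattern set/pattern")
        out[cause] = pats
    return out


def classify_admission(record, cause_map: dict) -> set[str]:
    """Causes matched by any of the record's first four diagnosis codes."""
    cmap = _normalize_cause_map(cause_map)
    dx = [record.get(c) for c in DX_COLUMNS] if isinstance(record, dict) \
        else [record[c] for c in DX_COLUMNS]
    dx = [d for d in dx if d is not None and not pd.isna(d)]
    return {cause for cause, pats in cmap.items()
            if any(_matches(d, pats) for d in dx)}


def classify_admissions(records: pd.DataFrame, cause_map: dict) -> pd.DataFrame:
    """Boolean indicator frame, one column per cause, aligned with records."""
    cmap = _normalize_cause_map(cause_map)
    dx = records[DX_COLUMNS].astype("string")
    norm = dx.apply(lambda col: col.str.strip().str.upper()
                    .str.replace(".", "", regex=False))
    out = pd.DataFrame(index=records.index)
    for cause, pats in cmap.items():
        hit = pd.Series(False, index=records.index)
        for p in pats:
            if len(p) >= 5:
                hit |= norm.eq(p).any(axis=1)
            else:
                hit |= norm.apply(lambda c: c.str.startswith(p)).fillna(
                    False).any(axis=1)
        out[cause] = hit
    return out


@dataclass
class ExclusionReport:
    n_in: int
    n_out: int
    reasons: dict[str, int]

    @property
    def percent_excluded(self) -> float:
        return exclusion_percent(self.n_in, self.n_out)


def exclusion_percent(n_in: int, n_out: int) -> float:
    """Percentage excluded, ``100 (n_in - n_out) / n_in``, to 1 decimal."""
    if n_in <= 0:
        return 0.0
    return round(100.0 * (n_in - n_out) / n_in, 1)


def apply_exclusions(records: pd.DataFrame, study_period: tuple | None = None
                     ) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop records with missing/unparseable sex, age, date or ZIP.

    "Inaccurate" dates are operationalized as unparseable or outside
    ``study_period`` when given.  Idempotent: a second application excludes
    nothing.
    """
    r = records.copy()
    if pd.api.types.is_datetime64_any_dtype(r["admission_date"]):
        dates = r["admission_date"]
    else:
        dates = pd.to_datetime(r["admission_date"], errors="coerce",
                               format="ISO8601")
    bad_date = dates.isna()
    if study_period is not None:
        start, end = pd.Timestamp(study_period[0]), pd.Timestamp(study_period[1])
        bad_date |= (dates < start) | (dates > end)
    ages = pd.to_numeric(r["age"], errors="coerce")
    bad_age = ages.isna() | (ages < 0) | (ages > 130)
    sex = r["sex"].astype("string").str.strip().str.lower()
    bad_sex = ~sex.isin(SEXES)
    zips = r["unit_id"].astype("string").str.strip()
    bad_zip = zips.isna() | (zips == "")

    bad = bad_date | bad_age | bad_sex | bad_zip
    reasons = {"date": int(bad_date.sum()), "age": int(bad_age.sum()),
               "sex": int(bad_sex.sum()), "zip": int(bad_zip.sum())}
    kept = r[~bad].copy()
    kept["admission_date"] = dates[~bad]
    kept["age"] = ages[~bad]
    kept["sex"] = sex[~bad]
    kept["unit_id"] = zips[~bad]
    report = ExclusionReport(n_in=len(r), n_out=len(kept), reasons=reasons)
    return kept.reset_index(drop=True), report


def assign_svi_tertiles(tract_svi: pd.DataFrame, area_weights: pd.DataFrame,
                        tol: float = 1e-9) -> pd.DataFrame:
    """Area-weight tract SVI values to units and split into tertiles.

    ``tract_svi``: columns (tract_id, svi_value in [0,1]);
    ``area_weights``: columns (tract_id, unit_id, weight) with per-unit
    weights summing to 1.  Units are ranked by SVI (ties broken by unit_id)
    and split low -> high into tertiles 1..3 whose sizes differ by at most 1.
    """
    sums = area_weights.groupby("unit_id")["weight"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if len(bad):
        raise ValueError(f"area weights do not sum to 1 for units "
                         f"{bad.index.tolist()[:5]}")
    vals = tract_svi.set_index("tract_id")["svi_value"]
    missing = set(area_weights["tract_id"]) - set(vals.index)
    if missing:
        raise ValueError(f"tracts without SVI values: {sorted(missing)[:5]!r}")
    w = area_weights.copy()
    w["value"] = vals.reindex(w["tract_id"]).to_numpy() * w["weight"].to_numpy()
    unit_svi = w.groupby("unit_id")["value"].sum().rename("svi_value")

    ranked = unit_svi.reset_index().sort_values(
        ["svi_value", "unit_id"], kind="stable").reset_index(drop=True)
    n = len(ranked)
    tertile = np.empty(n, dtype=int)
    bounds = [len(part) for part in np.array_split(np.arange(n), 3)]
    start = 0
    for t, size in enumerate(bounds, start=1):
        tertile[start:start + size] = t
        start += size
    ranked["tertile"] = tertile
    return ranked


def extract_case_series(records: pd.DataFrame, cause: str, cause_map: dict,
                        svi: pd.DataFrame, city_units) -> pd.DataFrame:
    """One CaseEvent row per retained record matching ``cause``.

    Attaches age group, location group (in/not in ``city_units``) and the
    unit's SVI tertile.  Exclusions must already have been applied.
    """
    flags = classify_admissions(records, {cause: cause_map[cause]})[cause]
    ev = records[flags].copy()
    ev["cause"] = cause
    ev["age_group"] = pd.cut(ev["age"], bins=AGE_BINS, labels=AGE_LABELS,
                             right=False).astype(str)
    city = set(city_units)
    ev["location_group"] = np.where(ev["unit_id"].isin(city),
                                    "in_city", "not_in_city")
    svi_idx = svi.set_index("unit_id")["tertile"]
    missing = set(ev["unit_id"]) - set(svi_idx.index)
    if missing:
        raise ValueError(f"units missing from SVI assignment: "
                         f"{sorted(missing)[:5]!r}")
    ev["svi_tertile"] = svi_idx.reindex(ev["unit_id"]).to_numpy()
    cols = ["record_id", "cause", "admission_date", "unit_id", "age",
            "age_group", "sex", "location_group", "svi_tertile"]
    return ev[cols].reset_index(drop=True)
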