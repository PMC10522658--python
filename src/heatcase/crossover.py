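"""Time-stratified case-crossover strata with lagged exposures.

In the time-stratified referent scheme, every case day is compared with the
other days of the same calendar month and year that share its day-of-week.
Matching on year-month and weekday controls season, long-term trend and
weekday patterns by design; because same-weekday days are 7 apart, the 0-6
day lag windows of case and control days never overlap.

Each case event becomes one stratum: the case day plus its 3-4 control days,
every day carrying lag-0..L vectors of temperature and relative humidity
looked up from the unit's exposure series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["enumerate_control_days", "build_strata", "StrataSet"]


def enumerate_control_days(case_date) -> list:
    """All other dates in the case date's calendar month sharing its
    day-of-week, ascending.

    A month contains a given weekday 4 or 5 times, so every stratum has 3 or
    4 control days.
    """
    d = pd.Timestamp(case_date)
    dom = d.day
    out = []
    for k in range(-4, 5):
        cand_day = dom + 7 * k
        if k == 0 or cand_day < 1 or cand_day > d.days_in_month:
            continue
        out.append((d.replace(day=cand_day)).date())
    return out


@dataclass
class StrataSet:
    """Case-crossover strata in flat array form.

    ``events`` holds one row per retained case event (the stratum order);
    the ``row_*`` arrays describe all case+control days, ``stratum_sizes[i]``
    consecutive rows per stratum ``i``.  Lag matrices have ``max_lag + 1``
    columns (lag 0 first).
    """

    events: pd.DataFrame
    row_stratum: np.ndarray      # int, index into events
    row_date: np.ndarray         # datetime64[D]
    row_is_case: np.ndarray      # 0/1
    lag_temperature: np.ndarray  # (n_rows, max_lag+1)
    lag_rh: np.ndarray           # (n_rows, max_lag+1)
    max_lag: int
    n_dropped_missing_history: int = 0

    @property
    def n_strata(self) -> int:
        return len(self.events)

    @property
    def stratum_sizes(self) -> np.ndarray:
        return np.bincount(self.row_stratum, minlength=self.n_strata)

    def subset(self, event_mask) -> "StrataSet":
        """Strata for a subset of events (e.g. one sex or age group)."""
        event_mask = np.asarray(event_mask, dtype=bool)
        keep_idx = np.flatnonzero(event_mask)
        remap = -np.ones(self.n_strata, dtype=int)
        remap[keep_idx] = np.arange(keep_idx.size)
        row_keep = event_mask[self.row_stratum]
        return StrataSet(
            events=self.events.iloc[keep_idx].reset_index(drop=True),
            row_stratum=remap[self.row_stratum[row_keep]],
            row_date=self.row_date[row_keep],
            row_is_case=self.row_is_case[row_keep],
            lag_temperature=self.lag_temperature[row_keep],
            lag_rh=self.lag_rh[row_keep],
            max_lag=self.max_lag,
            n_dropped_missing_history=self.n_dropped_missing_history,
        )

    def to_long_frame(self) -> pd.DataFrame:
        """Audit serialization: one row per (stratum day, lag index)."""
        n_rows = self.row_stratum.size
        L = self.max_lag + 1
        return pd.DataFrame({
            "stratum_id": np.repeat(self.row_stratum, L),
            "date": np.repeat(self.row_date, L),
            "is_case": np.repeat(self.row_is_case, L),
            "lag": np.tile(np.arange(L), n_rows),
            "temperature": self.lag_temperature.ravel(),
            "relative_humidity": self.lag_rh.ravel(),
        })


def build_strata(events: pd.DataFrame, exposure: pd.DataFrame,
                 max_lag: int = 6) -> StrataSet:
    """Build one time-stratified stratum per case event with lagged exposures.

    ``events`` needs columns ``admission_date`` and ``unit_id``; ``exposure``
    is a per-(unit, day) table with ``temperature`` and ``relative_humidity``.
    Row lag vector element ``l`` is the exposure at ``row date - l`` days.
    Events whose lag window reaches before the unit's exposure coverage are
    dropped (counted and logged); a gap inside coverage raises.
    """
    ev = events.reset_index(drop=True).copy()
    ev["admission_date"] = pd.to_datetime(ev["admission_date"])

    exp = exposure.copy()
    exp["date"] = pd.to_datetime(exp["date"])

    # per-unit dense arrays indexed by day offset from the unit's first day
    unit_arrays: dict = {}
    for unit, g in exp.groupby("unit_id", sort=False):
        g = g.sort_values("date")
        days = g["date"].values.astype("datetime64[D]")
        start, end = days[0], days[-1]
        n = int((end - start).astype(int)) + 1
        if len(g) != n:
            full = np.arange(start, end + np.timedelta64(1, "D"))
            missing = np.setdiff1d(full, days)
            raise ValueError(
                f"exposure gap for unit {unit!r}: first missing date {missing[0]}"
            )
        unit_arrays[unit] = (start, n, g["temperature"].to_numpy(float),
                             g["relative_humidity"].to_numpy(float))

    missing_units = set(ev["unit_id"]) - set(unit_arrays)
    if missing_units:
        raise ValueError(f"no exposure series for units {sorted(missing_units)!r}")

    lag_off = np.arange(max_lag + 1)
    strata_rows = []  # (event_idx, date, is_case)
    n_dropped = 0
    keep_event = np.ones(len(ev), dtype=bool)
    for i, (unit, cdate) in enumerate(zip(ev["unit_id"], ev["admission_date"])):
        start, n, _, _ = unit_arrays[unit]
        case_d = np.datetime64(cdate, "D")
        controls = enumerate_control_days(cdate)
        dates = sorted([case_d] + [np.datetime64(c, "D") for c in controls])
        offs = [int((d - start).astype(int)) for d in dates]
        if min(offs) - max_lag < 0 or max(offs) >= n:
            if max(offs) >= n or min(offs) < 0:
                raise ValueError(
                    f"exposure for unit {unit!r} does not cover stratum dates "
                    f"around {cdate.date()}"
                )
            n_dropped += 1
            keep_event[i] = False
            continue
        for d, o in zip(dates, offs):
            strata_rows.append((i, unit, o, int(d == case_d), d))

    if n_dropped:
        logger.info("dropped %d events lacking full %d-day lag history",
                    n_dropped, max_lag)
    if not strata_rows:
        raise ValueError("no strata could be built")

    old_idx = np.array([r[0] for r in strata_rows])
    remap = -np.ones(len(ev), dtype=int)
    remap[np.flatnonzero(keep_event)] = np.arange(int(keep_event.sum()))
    row_stratum = remap[old_idx]
    row_is_case = np.array([r[3] for r in strata_rows], dtype=np.int8)
    row_date = np.array([r[4] for r in strata_rows], dtype="datetime64[D]")

    n_rows = len(strata_rows)
    lag_t = np.empty((n_rows, max_lag + 1))
    lag_r = np.empty((n_rows, max_lag + 1))
    for j, (_, unit, o, _, _) in enumerate(strata_rows):
        _, _, t_arr, r_arr = unit_arrays[unit]
        idx = o - lag_off
        lag_t[j] = t_arr[idx]
        lag_r[j] = r_arr[idx]

    return StrataSet(
        events=ev[keep_event].reset_index(drop=True),
        row_stratum=row_stratum,
        row_date=row_date,
        row_is_case=row_is_case,
        lag_temperature=lag_t,
        lag_rh=lag_r,
        max_lag=max_lag,
        n_dropped_missing_history=n_dropped,
    )
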