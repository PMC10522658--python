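"""Published summary numbers used for internal-consistency checks.

The statewide hospital microdata behind the original 1995-2014 New York
State analysis are access-restricted, but its published demographic summary
table and a handful of printed totals are reproducible arithmetic.  This
module ships those summary counts as package data and recomputes the derived
quantities (percentages, exclusion rates, tertile sizes) from them.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .cohort import exclusion_percent

__all__ = ["load_demographics_table", "demographic_percentages",
           "check_table_consistency", "PRINTED_TOTALS"]

# raw and complete record totals per cause (records before/after exclusions)
PRINTED_TOTALS = {
    "alcohol_related": {"raw": 717_798, "complete": 671_625},
    "substance_related": {"raw": 794_305, "complete": 721_469},
}


def load_demographics_table() -> pd.DataFrame:
    """Cause x characteristic x level counts for the complete records."""
    with resources.files("heatcase.data").joinpath(
            "table1_demographics.csv").open() as fh:
        return pd.read_csv(fh)


def demographic_percentages(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Percentages of each level within (cause, characteristic), 1 decimal."""
    t = load_demographics_table() if table is None else table.copy()
    t["percent"] = (100.0 * t["count"] / t["total"]).round(1)
    return t


def check_table_consistency(table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per (cause, characteristic): do the level counts sum to the total?

    Returns one row per group with the recomputed sum and the discrepancy.
    """
    t = load_demographics_table() if table is None else table
    g = (t.groupby(["cause", "characteristic"])
         .agg(total=("total", "first"), level_sum=("count", "sum"))
         .reset_index())
    g["discrepancy"] = g["level_sum"] - g["total"]
    return g


def recomputed_exclusion_percents() -> dict[str, float]:
    """Exclusion percentages from the raw/complete totals."""
    return {cause: exclusion_percent(v["raw"], v["complete"])
            for cause, v in PRINTED_TOTALS.items()}
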