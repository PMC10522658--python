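"""Cause classification, exclusions, SVI tertiles and case-series extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatcase.cohort import (apply_exclusions, assign_svi_tertiles,
                             classify_admission, classify_admissions,
                             exclusion_percent, extract_case_series)


def record(dx, **kw):
    base = {"record_id": "r1", "admission_date": "2001-06-05",
            "unit_id": "z1", "age": 30, "sex": "male",
            "admission_type": "inpatient"}
    for i in range(4):
        base[f"dx{i+1}"] = dx[i] if i < len(dx) else None
    base.update(kw)
    return base


class TestClassify:
    def test_first_position_match(self):
        assert classify_admission(record(["3040", "x", "y", "z"]),
                                  {"A": {"3040"}}) == {"A"}

    def test_only_first_four_positions_exist(self):
        # codes beyond diagnostic position 4 are never ingested: a record
        # whose only matching code sat at position 5 in the source carries
        # no match in its four dx fields
        rec = record(["4019", "25000", "486", "311"])
        assert classify_admission(rec, {"A": {"3049"}}) == set()

    def test_one_admission_several_causes(self):
        rec = record(["3040", "2920", None, None])
        out = classify_admission(rec, {"A": {"3040"}, "B": {"292"}})
        assert out == {"A", "B"}

    def test_prefix_matches_subcodes(self):
        # 304.3 as a 4-digit pattern covers 304.30-304.39
        for code in ["30430", "30435", "30439"]:
            assert classify_admission(record([code]), {"A": {"304.3"}}) == {"A"}
        assert classify_admission(record(["30530"]), {"A": {"304.3"}}) == set()

    def test_exact_5digit_pattern(self):
        assert classify_admission(record(["30531"]), {"A": {"30530"}}) == set()
        assert classify_admission(record(["30530"]), {"A": {"30530"}}) == {"A"}

    def test_vectorized_agrees_with_scalar(self, rng):
        codes = ["291", "303", "3050", "304", "4019", "486"]
        recs = pd.DataFrame([record([rng.choice(codes) for _ in range(4)],
                                    record_id=f"r{i}") for i in range(40)])
        cmap = {"alc": ["291", "303", "3050"], "sub": ["304"]}
        flags = classify_admissions(recs, cmap)
        for i, row in recs.iterrows():
            assert set(flags.columns[flags.loc[i]]) == \
                classify_admission(row.to_dict(), cmap)

    def test_empty_pattern_set_rejected(self):
        with pytest.raises(ValueError):
            classify_admission(record(["3040"]), {"A": set()})


class TestExclusions:
    def _records(self, n=10):
        return pd.DataFrame([record(["3040"], record_id=f"r{i}")
                             for i in range(n)])

    def test_complete_records_kept(self):
        kept, rep = apply_exclusions(self._records())
        assert rep.n_in == rep.n_out == 10
        assert rep.percent_excluded == 0.0

    def test_missing_zip_excluded(self):
        recs = self._records()
        recs.loc[3, "unit_id"] = ""
        kept, rep = apply_exclusions(recs)
        assert rep.n_out == 9
        assert rep.reasons["zip"] == 1
        assert "r3" not in set(kept["record_id"])

    @pytest.mark.parametrize("col,val", [
        ("sex", "unknown"), ("age", "??"), ("admission_date", "not-a-date"),
        ("age", -3),
    ])
    def test_unparseable_fields_excluded(self, col, val):
        recs = self._records()
        recs[col] = recs[col].astype(object)
        recs.loc[0, col] = val
        _, rep = apply_exclusions(recs)
        assert rep.n_out == 9

    def test_date_outside_period_excluded(self):
        recs = self._records()
        recs.loc[0, "admission_date"] = "1980-01-01"
        _, rep = apply_exclusions(recs, study_period=("2001-01-01",
                                                      "2001-12-31"))
        assert rep.n_out == 9

    def test_idempotent(self):
        recs = self._records()
        recs.loc[0, "unit_id"] = ""
        kept1, _ = apply_exclusions(recs)
        kept2, rep2 = apply_exclusions(kept1)
        assert rep2.n_in == rep2.n_out == len(kept1)

    def test_printed_exclusion_percentage(self):
        # recomputed from the published raw/complete record totals
        assert exclusion_percent(794_305, 721_469) == 9.2


class TestSviTertiles:
    def test_single_tract_passthrough(self):
        svi = pd.DataFrame({"tract_id": ["t1"], "svi_value": [0.37]})
        aw = pd.DataFrame({"tract_id": ["t1"], "unit_id": ["u1"],
                           "weight": [1.0]})
        out = assign_svi_tertiles(svi, aw)
        assert out["svi_value"].iloc[0] == pytest.approx(0.37)

    def test_hand_arithmetic(self):
        svi = pd.DataFrame({"tract_id": ["t1", "t2"],
                            "svi_value": [0.2, 0.6]})
        aw = pd.DataFrame({"tract_id": ["t1", "t2"], "unit_id": ["u1", "u1"],
                           "weight": [0.5, 0.5]})
        out = assign_svi_tertiles(svi, aw)
        assert out["svi_value"].iloc[0] == pytest.approx(0.4)

    def test_1794_units_give_598_per_tertile(self, rng):
        n = 1794
        svi = pd.DataFrame({"tract_id": [f"t{i}" for i in range(n)],
                            "svi_value": rng.uniform(size=n)})
        aw = pd.DataFrame({"tract_id": svi["tract_id"],
                           "unit_id": [f"u{i}" for i in range(n)],
                           "weight": 1.0})
        out = assign_svi_tertiles(svi, aw)
        assert out.groupby("tertile").size().tolist() == [598, 598, 598]

    def test_sizes_differ_by_at_most_one(self, rng):
        for n in (7, 8, 9):
            svi = pd.DataFrame({"tract_id": [f"t{i}" for i in range(n)],
                                "svi_value": rng.uniform(size=n)})
            aw = pd.DataFrame({"tract_id": svi["tract_id"],
                               "unit_id": [f"u{i}" for i in range(n)],
                               "weight": 1.0})
            sizes = assign_svi_tertiles(svi, aw).groupby("tertile").size()
            assert sizes.max() - sizes.min() <= 1

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_to_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        vals = rng.uniform(size=n)
        svi = pd.DataFrame({"tract_id": [f"t{i}" for i in range(n)],
                            "svi_value": vals})
        aw = pd.DataFrame({"tract_id": svi["tract_id"],
                           "unit_id": [f"u{i}" for i in range(n)],
                           "weight": 1.0})
        base = assign_svi_tertiles(svi, aw).set_index("unit_id")["tertile"]
        svi2 = svi.assign(svi_value=vals**3 * 0.999)  # order-preserving
        trans = assign_svi_tertiles(svi2, aw).set_index("unit_id")["tertile"]
        assert (base == trans.reindex(base.index)).all()

    def test_bad_area_weights_rejected(self):
        svi = pd.DataFrame({"tract_id": ["t1"], "svi_value": [0.5]})
        aw = pd.DataFrame({"tract_id": ["t1"], "unit_id": ["u1"],
                           "weight": [0.9]})
        with pytest.raises(ValueError, match="sum to 1"):
            assign_svi_tertiles(svi, aw)


class TestExtractCaseSeries:
    def _setup(self):
        recs = pd.DataFrame(
            [record(["3040"], record_id=f"m{i}", unit_id="z1", age=a)
             for i, a in enumerate([24, 25, 44, 45, 64, 65])][:3]
            + [record(["4019"], record_id=f"n{i}", unit_id="z2")
               for i in range(2)])
        kept, _ = apply_exclusions(recs)
        svi = pd.DataFrame({"unit_id": ["z1", "z2"], "svi_value": [0.2, 0.8],
                            "tertile": [1, 3]})
        return kept, svi

    def test_only_matching_records(self):
        kept, svi = self._setup()
        ev = extract_case_series(kept, "opioids", {"opioids": ["3040"]},
                                 svi, {"z1"})
        assert len(ev) == 3
        assert (ev["location_group"] == "in_city").all()
        assert (ev["svi_tertile"] == 1).all()

    def test_age_bin_boundaries(self):
        recs = pd.DataFrame([record(["3040"], record_id=f"r{a}", age=a)
                             for a in [0, 24, 25, 44, 45, 64, 65, 90]])
        kept, _ = apply_exclusions(recs)
        svi = pd.DataFrame({"unit_id": ["z1"], "svi_value": [0.5],
                            "tertile": [2]})
        ev = extract_case_series(kept, "c", {"c": ["3040"]}, svi, set())
        groups = ev.set_index("record_id")["age_group"]
        assert groups["r24"] == "0-24" and groups["r25"] == "25-44"
        assert groups["r44"] == "25-44" and groups["r45"] == "45-64"
        assert groups["r64"] == "45-64" and groups["r65"] == "65+"

    def test_multicause_record_in_both_series(self):
        recs = pd.DataFrame([record(["3040", "2920"], record_id="both")])
        kept, _ = apply_exclusions(recs)
        svi = pd.DataFrame({"unit_id": ["z1"], "svi_value": [0.5],
                            "tertile": [2]})
        cmap = {"A": ["3040"], "B": ["292"]}
        for cause in ("A", "B"):
            ev = extract_case_series(kept, cause, cmap, svi, set())
            assert list(ev["record_id"]) == ["both"]

    def test_unit_missing_from_svi_listed(self):
        kept, svi = self._setup()
        with pytest.raises(ValueError, match="z1"):
            extract_case_series(kept, "c", {"c": ["3040"]},
                                svi[svi["unit_id"] != "z1"], set())

    def test_multicause_counts_at_least_distinct_records(self, rng):
        # sum over causes of per-cause counts >= distinct retained records
        codes = ["3040", "2920", "291", "4019"]
        recs = pd.DataFrame([record([rng.choice(codes) for _ in range(2)],
                                    record_id=f"r{i}") for i in range(50)])
        kept, _ = apply_exclusions(recs)
        cmap = {"A": ["3040"], "B": ["292"], "C": ["291"], "D": ["4019"]}
        flags = classify_admissions(kept, cmap)
        assert flags.sum().sum() >= flags.any(axis=1).sum()
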