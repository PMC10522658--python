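"""Synthetic weather, admissions and fixture-bundle generation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from heatcase.crossover import build_strata
from heatcase.simulate import (DEFAULT_CAUSE_MAP, LinearSurface, NullSurface,
                               SimulationTruth, ThresholdSurface,
                               WeatherParams, simulate_admissions,
                               simulate_weather, surface_from_dict,
                               write_fixture_bundle)
from heatcase.weather import compute_relative_humidity


class TestSimulateWeather:
    def test_no_amplitude_no_noise_is_constant(self):
        truth = SimulationTruth(weather=WeatherParams(
            amplitude=0.0, noise_sd=0.0, cell_offset_sd=0.0),
            n_cells=2, period=("2001-01-01", "2001-03-31"))
        g = simulate_weather(truth)
        assert g["temperature"].nunique() == 1

    def test_same_seed_reproducible(self):
        truth = SimulationTruth(n_cells=3, period=("2001-01-01", "2001-06-30"),
                                seed=9)
        a, b = simulate_weather(truth), simulate_weather(truth)
        pd.testing.assert_frame_equal(a, b)

    def test_deseasonalized_lag1_autocorrelation(self):
        ar1 = 0.6
        truth = SimulationTruth(
            weather=WeatherParams(ar1=ar1, cell_offset_sd=0.0),
            n_cells=1, period=("1990-01-01", "2017-05-18"), seed=3)
        g = simulate_weather(truth)
        n = len(g)
        assert n >= 10_000
        doy = np.arange(n, dtype=float)
        wp = truth.weather
        season = wp.mean + wp.amplitude * np.sin(
            2 * np.pi * (doy - wp.phase_days) / 365.25)
        anom = g["temperature"].to_numpy() - season
        anom -= anom.mean()
        acf1 = float(anom[1:] @ anom[:-1] / (anom @ anom))
        assert acf1 == pytest.approx(ar1, abs=0.03)

    def test_downstream_rh_in_open_range(self):
        truth = SimulationTruth(n_cells=4, period=("2001-01-01", "2002-12-31"),
                                seed=5)
        g = simulate_weather(truth)
        rh = compute_relative_humidity(g["temperature"],
                                       g["specific_humidity"], g["pressure"])
        assert (rh > 5.0).all() and (rh < 100.0).all()


def unit_exposure(truth, rng):
    g = simulate_weather(truth, rng)
    g = g[g["cell_id"] == g["cell_id"].iloc[0]]
    return pd.DataFrame({
        "unit_id": "u1", "date": g["date"],
        "temperature": g["temperature"].to_numpy(),
        "relative_humidity": compute_relative_humidity(
            g["temperature"], g["specific_humidity"], g["pressure"])})


class TestSimulateAdmissions:
    def test_zero_rate_zero_records(self):
        truth = SimulationTruth(baseline_log_rate=-np.inf, n_cells=1,
                                period=("2001-01-01", "2001-12-31"))
        rng = truth.rng()
        exp = unit_exposure(truth, rng)
        recs = simulate_admissions(truth, exp, rng=rng)
        assert len(recs) == 0

    def test_target_cases_calibration(self):
        truth = SimulationTruth(n_cells=1, period=("2001-01-01", "2002-12-31"),
                                seed=2)
        rng = truth.rng()
        exp = unit_exposure(truth, rng)
        recs = simulate_admissions(truth, exp, rng=rng, target_cases=3000)
        assert abs(len(recs) - 3000) < 4 * np.sqrt(3000)

    def test_records_match_cause_map(self):
        truth = SimulationTruth(n_cells=1, period=("2001-01-01", "2001-12-31"),
                                seed=4)
        rng = truth.rng()
        exp = unit_exposure(truth, rng)
        recs = simulate_admissions(truth, exp, rng=rng, target_cases=300)
        patterns = sorted({p for ps in DEFAULT_CAUSE_MAP.values() for p in ps})
        assert recs["dx1"].str.startswith(tuple(patterns)).all()
        assert recs["sex"].isin(["female", "male"]).all()

    def test_null_surface_case_days_uniform_within_strata(self):
        """Under a null surface the case day is uniform over its stratum's
        days: chi-square goodness of fit on case positions."""
        truth = SimulationTruth(surface=NullSurface(), n_cells=1,
                                period=("2001-01-01", "2003-12-31"), seed=6)
        rng = truth.rng()
        exp = unit_exposure(truth, rng)
        recs = simulate_admissions(truth, exp, rng=rng, target_cases=4000)
        strata = build_strata(recs[["admission_date", "unit_id"]], exp)
        pos, sizes = [], strata.stratum_sizes
        for i in range(strata.n_strata):
            rows = np.flatnonzero(strata.row_stratum == i)
            pos.append(int(np.flatnonzero(
                strata.row_is_case[rows])[0]))
        pos, sizes = np.asarray(pos), np.asarray(sizes)
        for size in (4, 5):
            sel = sizes == size
            if sel.sum() < 100:
                continue
            obs = np.bincount(pos[sel], minlength=size)
            chi2, p = stats.chisquare(obs)
            assert p > 0.01

    def test_case_day_distribution_follows_softmax(self):
        """With a strong linear surface, empirical case-day frequencies track
        the softmax of the true cumulative linear predictor."""
        surf = LinearSurface(slope_per_degc=0.08, reference=0.0)
        truth = SimulationTruth(surface=surf, n_cells=1,
                                period=("2001-01-01", "2003-12-31"), seed=8)
        rng = truth.rng()
        exp = unit_exposure(truth, rng)
        recs = simulate_admissions(truth, exp, rng=rng, target_cases=6000)
        strata = build_strata(recs[["admission_date", "unit_id"]], exp)
        obs = np.zeros(4)
        expe = np.zeros(4)
        for i in range(strata.n_strata):
            rows = np.flatnonzero(strata.row_stratum == i)
            if rows.size != 4:
                continue
            eta = strata.lag_temperature[rows].sum(axis=1) \
                * surf.slope_per_degc / 7.0
            p = np.exp(eta - eta.max())
            p /= p.sum()
            expe += p
            obs[int(np.flatnonzero(strata.row_is_case[rows])[0])] += 1
        chi2 = ((obs - expe) ** 2 / expe).sum()
        assert stats.chi2.sf(chi2, df=3) > 0.01

    def test_contamination_exercises_exclusions(self):
        from heatcase.cohort import apply_exclusions

        truth = SimulationTruth(n_cells=1, period=("2001-01-01", "2001-12-31"),
                                seed=10)
        rng = truth.rng()
        exp = unit_exposure(truth, rng)
        recs = simulate_admissions(truth, exp, rng=rng, target_cases=1000,
                                   contamination=0.1)
        _, rep = apply_exclusions(recs)
        assert rep.n_in - rep.n_out == pytest.approx(100, abs=30)


class TestSurfaces:
    def test_surfaces_vanish_at_reference(self):
        for s in (NullSurface(), LinearSurface(0.02, reference=-5.0),
                  ThresholdSurface(0.02, reference=-5.0, threshold=18.0)):
            for l in range(7):
                assert float(np.asarray(s(s.reference, l))) == 0.0

    def test_linear_cumulative(self):
        s = LinearSurface(slope_per_degc=0.02, reference=-5.0)
        assert s.cumulative(5.0) == pytest.approx(0.2)

    def test_threshold_flat_above(self):
        s = ThresholdSurface(slope_per_degc=0.02, reference=-5.0,
                             threshold=18.0)
        assert s.cumulative(25.0) == pytest.approx(s.cumulative(18.0))

    def test_roundtrip_through_dict(self):
        for s in (NullSurface(), LinearSurface(0.03, reference=-2.0),
                  ThresholdSurface(0.01, reference=0.0, threshold=15.0)):
            s2 = surface_from_dict(s.to_dict())
            assert s2 == s


class TestFixtureBundle:
    def test_roundtrip_through_readers(self, fixture_bundle):
        from heatcase.io import load_bundle

        b = load_bundle(fixture_bundle)
        assert set(b) == {"grid", "population_weights", "area_weights",
                          "tract_svi", "admissions", "cause_map",
                          "city_units"}
        assert len(b["admissions"]) > 0

    def test_manifest_surface_identifiable(self, fixture_bundle):
        import yaml

        doc = yaml.safe_load((fixture_bundle / "truth.yaml").read_text())
        surf = surface_from_dict(doc["surface"])
        for l in range(7):
            assert float(np.asarray(surf(surf.reference, l))) == 0.0

    def test_two_seeds_differ_same_schema(self, tmp_path):
        t1 = SimulationTruth(n_units=2, n_cells=2,
                             period=("2001-01-01", "2001-12-31"), seed=1)
        t2 = SimulationTruth(n_units=2, n_cells=2,
                             period=("2001-01-01", "2001-12-31"), seed=2)
        write_fixture_bundle(t1, tmp_path / "a", target_cases=200,
                             contamination=0.0)
        write_fixture_bundle(t2, tmp_path / "b", target_cases=200,
                             contamination=0.0)
        a = pd.read_csv(tmp_path / "a" / "weather_grid.csv")
        b = pd.read_csv(tmp_path / "b" / "weather_grid.csv")
        assert list(a.columns) == list(b.columns)
        assert not np.allclose(a["temperature"], b["temperature"])

    def test_overwrite_guard(self, tmp_path):
        t = SimulationTruth(n_units=2, n_cells=2,
                            period=("2001-01-01", "2001-12-31"))
        write_fixture_bundle(t, tmp_path / "c", target_cases=100)
        with pytest.raises(FileExistsError):
            write_fixture_bundle(t, tmp_path / "c", target_cases=100)
        write_fixture_bundle(t, tmp_path / "c", target_cases=100,
                             overwrite=True)


class TestPower:
    def test_ci_width_shrinks_with_case_count(self):
        """At a fixed surface the cumulative-contrast CI narrows as the
        simulated case count grows."""
        from heatcase.experiments import replicate_contrast_experiment

        surf = LinearSurface(slope_per_degc=0.02, reference=-10.0)
        small = replicate_contrast_experiment(surf, 3, 400, seed=21,
                                              include_rh=False)
        large = replicate_contrast_experiment(surf, 3, 3200, seed=21,
                                              include_rh=False)
        assert large["se"].mean() < small["se"].mean()
        # and the estimate error shrinks too
        assert (large["estimate"] - large["truth"]).abs().mean() < \
            (small["estimate"] - small["truth"]).abs().mean()
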