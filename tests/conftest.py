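import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """A small synthetic input bundle written to disk once per session."""
    from heatcase.simulate import LinearSurface, SimulationTruth, \
        write_fixture_bundle

    out = tmp_path_factory.mktemp("bundle") / "b"
    truth = SimulationTruth(
        surface=LinearSurface(slope_per_degc=0.02, reference=-10.0),
        n_units=6, n_cells=4, period=("2001-01-01", "2002-12-31"), seed=42)
    write_fixture_bundle(truth, out, target_cases=2500, contamination=0.02)
    return out


@pytest.fixture(scope="session")
def small_strata():
    """A modest stratum set from a linear-surface simulation (session cache)."""
    from heatcase.experiments import simulate_strata
    from heatcase.simulate import LinearSurface, SimulationTruth

    truth = SimulationTruth(
        surface=LinearSurface(slope_per_degc=0.02, reference=-10.0),
        n_units=3, n_cells=3, period=("2001-01-01", "2002-12-31"), seed=7)
    return simulate_strata(truth, np.random.default_rng(7), target_cases=1200)


def random_strata(rng, n_strata=20, max_rows=5, n_cov=6, scale=1.0):
    """Random stratified design for likelihood oracle tests."""
    out = []
    for _ in range(n_strata):
        rows = int(rng.integers(2, max_rows + 1))
        x = rng.normal(0, scale, (rows, n_cov))
        out.append((int(rng.integers(rows)), x))
    return out
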