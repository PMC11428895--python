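import numpy as np
import pandas as pd
import pytest

from pigspread import synth
from pigspread.pipeline import RunConfig


@pytest.fixture(scope="session")
def landscape():
    """36-county 6x6 grid with 6 coarse watersheds of 5 fine units."""
    return synth.make_landscape(36, 6, 5, seed=11)


@pytest.fixture(scope="session")
def history(landscape):
    occupancy, huc12 = synth.make_history(
        landscape, range(2004, 2022), seed=12,
        invasion_years=range(2010, 2014),
    )
    return occupancy, huc12


@pytest.fixture(scope="session")
def covariates(landscape):
    return synth.make_covariates(landscape, range(2004, 2022), seed=13)


@pytest.fixture(scope="session")
def ledger(landscape):
    return synth.make_resources(landscape, seed=14)


@pytest.fixture()
def small_config(tmp_path):
    """Desk-scale pipeline config that runs in seconds."""
    return RunConfig(
        seed=5,
        out_dir=str(tmp_path / "run"),
        reps=10,
        n_rounds=30,
        n_counties=64,
        n_coarse=8,
        fine_per_coarse=6,
        min_stratum_rows=5,
    )


class StubPredictor:
    """Test double: delta model driven by a plain function of features."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.fn(X), dtype=float)


@pytest.fixture()
def stub_predictor():
    return StubPredictor


class FixedRate:
    """Test double for beta rate draws: always returns the same rate."""

    def __init__(self, value: float):
        self.value = float(value)

    def draw(self, rng) -> float:
        return self.value


@pytest.fixture()
def fixed_rate():
    return FixedRate


def chain_landscape(n: int = 3, area: float = 1000.0) -> synth.Landscape:
    """1xN chain of counties (queen adjacency = immediate neighbors)."""
    counties = pd.DataFrame(
        {
            "county_id": range(n),
            "state_id": ["S00"] * n,
            "area_km2": [area] * n,
            "cx": [float(i) for i in range(n)],
            "cy": [0.0] * n,
        }
    )
    pairs = [(i, i + 1) for i in range(n - 1)] + [(i + 1, i) for i in range(n - 1)]
    adjacency = pd.DataFrame(pairs, columns=["county_id", "neighbor_id"])
    watersheds = pd.DataFrame(
        {"huc8_id": [0], "region": ["west"], "cx": [0.0], "cy": [0.0]}
    )
    fine_units = pd.DataFrame(
        {"huc12_id": [0], "huc8_id": [0], "cx": [0.0], "cy": [0.0]}
    )
    overlap = pd.DataFrame(
        {"county_id": range(n), "huc8_id": [0] * n, "weight": [1.0] * n}
    )
    return synth.Landscape(counties, adjacency, watersheds, fine_units, overlap)


@pytest.fixture()
def chain3():
    return chain_landscape(3)


def crossing_history(n_up, n_down, window, n_extra=10, seed=0):
    """Occupancy history with exactly n_up upward and n_down downward
    threshold crossings spread round-robin over the window year-pairs.

    Extra counties stay occupied throughout; upward crossers establish
    at a seeded random proportion.
    """
    rng = np.random.default_rng(seed)
    years = [window[0] - 1] + list(window)
    rows = []
    cid = 0
    for j in range(n_up):
        y = window[j % len(window)]
        est = float(rng.uniform(0.1, 0.9))
        rows += [(cid, yr, 0.0 if yr < y else est) for yr in years]
        cid += 1
    for j in range(n_down):
        y = window[j % len(window)]
        rows += [(cid, yr, 0.5 if yr < y else 0.0) for yr in years]
        cid += 1
    for _ in range(n_extra):
        rows += [(cid, yr, 0.8) for yr in years]
        cid += 1
    return pd.DataFrame(rows, columns=["county_id", "year", "prop_occupied"])


def static_covariates(landscape, year: int = 2013) -> pd.DataFrame:
    """All-zero covariate table for stub-driven forecasts."""
    ids = landscape.county_ids
    return pd.DataFrame(
        {
            "county_id": ids,
            "year": year,
            "removals": 0.0,
            "active_removal_prop": 0.0,
            "hsi": 0.0,
            "density": 0.0,
            "pct_hydrology": 0.0,
            "pct_tree": 0.0,
            "pct_crop": 0.0,
            "pct_pasture": 0.0,
            "pct_deciduous": 0.0,
        }
    )
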