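"""Synthetic county/watershed landscape generation.

Builds desk-scale stand-ins for the national county and hydrologic-unit
data: a rectangular county grid with queen adjacency, a two-level
watershed hierarchy (coarse units containing fine replicate units),
occupancy histories with a persistent core and a transient fringe,
covariate surfaces, and agricultural resource/price tables.

The spread-rate delta generator uses a spike-at-zero plus gamma-tail
mixture. This family is a stand-in chosen to match the qualitative shape
of observed annual deltas (mass near zero, short negative tail, long
positive tail); no specific parametric form is implied by the source
data.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .valuation import km2_to_acres

REGIONS = ("west", "plains", "great_lakes", "east")

#: default spread-delta mixture parameters (see make_history)
DEFAULT_KERNEL = {
    "zero_prob": 0.50,   # P(no change in a county-year)
    "neg_prob": 0.18,    # P(negative | change)
    "neg_shape": 1.5,
    "neg_scale": 0.03,
    "pos_shape": 1.2,
    "pos_scale": 0.08,
}


@dataclass(frozen=True)
class Landscape:
    """Synthetic landscape: counties, watershed hierarchy, overlaps."""

    counties: pd.DataFrame       # county_id, state_id, area_km2, cx, cy
    adjacency: pd.DataFrame      # county_id, neighbor_id (symmetric pairs)
    watersheds: pd.DataFrame     # huc8_id, region, cx, cy
    fine_units: pd.DataFrame     # huc12_id, huc8_id, cx, cy
    overlap: pd.DataFrame        # county_id, huc8_id, weight

    @property
    def county_ids(self) -> np.ndarray:
        return self.counties["county_id"].to_numpy()

    @property
    def areas(self) -> pd.Series:
        return self.counties.set_index("county_id")["area_km2"]

    @property
    def states(self) -> pd.Series:
        return self.counties.set_index("county_id")["state_id"]

    def neighbors(self) -> dict[int, list[int]]:
        """Adjacency as a dict of sorted neighbor lists."""
        out: dict[int, list[int]] = {int(c): [] for c in self.county_ids}
        for c, n in self.adjacency.itertuples(index=False):
            out[int(c)].append(int(n))
        return {c: sorted(v) for c, v in out.items()}

    def fine_to_coarse(self) -> pd.Series:
        return self.fine_units.set_index("huc12_id")["huc8_id"]


@dataclass(frozen=True)
class SyntheticTruth:
    """Generating parameters recorded for recovery tests."""

    coefficients: pd.Series            # per six-predictor name
    intercept: float
    inv_beta: tuple[float, float]      # (alpha, beta) invasion rates
    ext_beta: tuple[float, float]      # (alpha, beta) extinction rates
    seed: int
    inv_rate_draws: np.ndarray = field(default_factory=lambda: np.empty(0))
    ext_rate_draws: np.ndarray = field(default_factory=lambda: np.empty(0))


def _grid_shape(n_counties: int) -> tuple[int, int]:
    """Closest-to-square factor pair (rows, cols) with rows*cols == n."""
    r = int(math.isqrt(n_counties))
    while n_counties % r != 0:
        r -= 1
    return r, n_counties // r


def make_landscape(
    n_counties: int,
    n_coarse_watersheds: int,
    fine_per_coarse: int,
    seed: int,
    *,
    n_states: int = 4,
    mean_area_km2: float = 1500.0,
    area_sigma: float = 0.35,
    overlap_temperature: float = 1.0,
) -> Landscape:
    """Build a rectangular-grid landscape with queen adjacency.

    County areas are log-normal around ``mean_area_km2``; coarse
    watershed centroids are scattered over the grid extent, and each
    county's overlap weights over coarse watersheds come from a
    centroid-distance softmax with the given temperature. Exactly four
    region labels (longitude quartiles) are assigned to coarse
    watersheds.
    """
    if n_counties < 4:
        raise ValueError("n_counties must be >= 4")
    if n_coarse_watersheds < 1 or fine_per_coarse < 1:
        raise ValueError("watershed counts must be positive")
    if n_states < 1:
        raise ValueError("n_states must be positive")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    nrow, ncol = _grid_shape(n_counties)
    cell = math.sqrt(mean_area_km2)  # nominal cell edge, km

    rows, cols = np.divmod(np.arange(n_counties), ncol)
    cx = (cols + 0.5) * cell
    cy = (rows + 0.5) * cell
    areas = mean_area_km2 * rng.lognormal(
        -0.5 * area_sigma**2, area_sigma, n_counties
    )
    # vertical state bands
    state_band = np.minimum((cols * n_states) // ncol, n_states - 1)
    counties = pd.DataFrame(
        {
            "county_id": np.arange(n_counties),
            "state_id": [f"S{b:02d}" for b in state_band],
            "area_km2": areas,
            "cx": cx,
            "cy": cy,
        }
    )

    pairs = []
    for i in range(n_counties):
        r, c = divmod(i, ncol)
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < nrow and 0 <= cc < ncol:
                pairs.append((i, rr * ncol + cc))
    adjacency = pd.DataFrame(pairs, columns=["county_id", "neighbor_id"])

    wx = rng.uniform(0, ncol * cell, n_coarse_watersheds)
    wy = rng.uniform(0, nrow * cell, n_coarse_watersheds)
    # region label by longitude quartile; each quartile nonempty when
    # n_coarse_watersheds >= 4
    order = np.argsort(wx, kind="stable")
    region = np.empty(n_coarse_watersheds, dtype=object)
    for lab, chunk in zip(REGIONS, np.array_split(order, 4)):
        region[chunk] = lab
    watersheds = pd.DataFrame(
        {
            "huc8_id": np.arange(n_coarse_watersheds),
            "region": region,
            "cx": wx,
            "cy": wy,
        }
    )

    fine_rows = []
    for w in range(n_coarse_watersheds):
        fx = wx[w] + rng.normal(0, 0.6 * cell, fine_per_coarse)
        fy = wy[w] + rng.normal(0, 0.6 * cell, fine_per_coarse)
        for j in range(fine_per_coarse):
            fine_rows.append((w * fine_per_coarse + j, w, fx[j], fy[j]))
    fine_units = pd.DataFrame(
        fine_rows, columns=["huc12_id", "huc8_id", "cx", "cy"]
    )

    # county -> coarse-watershed weights: softmax of -distance/temperature
    d = np.hypot(cx[:, None] - wx[None, :], cy[:, None] - wy[None, :])
    scale = overlap_temperature * cell
    logits = -d / scale
    logits -= logits.max(axis=1, keepdims=True)
    w = np.exp(logits)
    w /= w.sum(axis=1, keepdims=True)
    overlap = pd.DataFrame(
        {
            "county_id": np.repeat(np.arange(n_counties), n_coarse_watersheds),
            "huc8_id": np.tile(np.arange(n_coarse_watersheds), n_counties),
            "weight": w.ravel(),
        }
    )

    return Landscape(counties, adjacency, watersheds, fine_units, overlap)


def _draw_deltas(rng: np.random.Generator, n: int, kp: Mapping[str, float]) -> np.ndarray:
    """Spike-at-zero + two-sided gamma mixture of annual proportion deltas."""
    out = np.zeros(n)
    change = rng.random(n) >= kp["zero_prob"]
    neg = change & (rng.random(n) < kp["neg_prob"])
    pos = change & ~neg
    out[neg] = -rng.gamma(kp["neg_shape"], kp["neg_scale"], int(neg.sum()))
    out[pos] = rng.gamma(kp["pos_shape"], kp["pos_scale"], int(pos.sum()))
    return out


def make_history(
    landscape: Landscape,
    years: Sequence[int],
    persistent_frac: float = 0.29,
    transient_frac: float = 0.40,
    kernel_params: Mapping[str, float] | None = None,
    seed: int = 0,
    invasion_years: Sequence[int] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate county occupancy history and fine-watershed statuses.

    Returns ``(occupancy, huc12_status)``:

    * occupancy: county_id, year, prop_occupied — persistent counties
      keep a strictly positive proportion in every year; transient
      counties start unoccupied and invade in a later year (possibly
      retreating to zero afterwards); the rest stay at zero.
    * huc12_status: huc12_id, year, invaded — fine-watershed flags whose
      per-coarse-unit invaded fraction tracks the overlap-weighted
      county occupancy.

    ``invasion_years`` restricts the years transient counties can first
    invade (default: any year after the first), e.g. to concentrate
    toggles inside a stratification window.
    """
    years = list(years)
    if len(years) == 0:
        raise ValueError("empty year range")
    if not (0 <= persistent_frac <= 1 and 0 <= transient_frac <= 1):
        raise ValueError("fractions must be in [0, 1]")
    if persistent_frac + transient_frac > 1 + 1e-12:
        raise ValueError("persistent_frac + transient_frac must be <= 1")

    kp = dict(DEFAULT_KERNEL)
    if kernel_params:
        kp.update(kernel_params)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 202]))

    ids = landscape.county_ids
    n = len(ids)
    n_pers = int(round(persistent_frac * n))
    n_trans = min(int(round(transient_frac * n)), n - n_pers)
    perm = rng.permutation(n)
    persistent = ids[perm[:n_pers]]
    transient = ids[perm[n_pers:n_pers + n_trans]]

    p = pd.DataFrame(0.0, index=ids, columns=years)
    floor = 0.01  # persistent counties never fall to zero

    p0 = rng.uniform(0.2, 0.9, n_pers)
    p.loc[persistent, years[0]] = p0
    for t_prev, t in zip(years, years[1:]):
        d = _draw_deltas(rng, n_pers, kp)
        p.loc[persistent, t] = np.clip(
            p.loc[persistent, t_prev].to_numpy() + d, floor, 1.0
        )

    if len(years) > 1 and n_trans:
        if invasion_years is None:
            allowed = np.arange(1, len(years))
        else:
            allowed = np.array(
                [years.index(y) for y in invasion_years if y in years[1:]]
            )
            if len(allowed) == 0:
                raise ValueError("invasion_years has no year after the first")
        inv_year_idx = rng.choice(allowed, n_trans)
        establish = rng.beta(2.0, 8.0, n_trans)
        for k, cid in enumerate(transient):
            iy = inv_year_idx[k]
            p.loc[cid, years[iy]] = max(establish[k], floor)
            for j in range(iy + 1, len(years)):
                d = _draw_deltas(rng, 1, kp)[0]
                p.loc[cid, years[j]] = float(
                    np.clip(p.loc[cid, years[j - 1]] + d, 0.0, 1.0)
                )

    occupancy = (
        p.rename_axis("county_id")
        .reset_index()
        .melt("county_id", var_name="year", value_name="prop_occupied")
        .sort_values(["year", "county_id"], ignore_index=True)
    )

    huc12 = _fine_status_from_occupancy(landscape, p, rng)
    return occupancy, huc12


def _fine_status_from_occupancy(
    landscape: Landscape, p: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Fine-unit flags whose coarse fractions track county occupancy.

    Each coarse watershed w gets a target invaded fraction per year equal
    to the county-overlap-weighted mean of county proportions; the count
    of flagged fine units is round(target * n_fine) plus an occasional
    ±1 jitter, assigned in a fixed random priority order — statuses
    track county occupancy closely yet annual invasion/extinction rates
    stay stochastic.
    """
    w = landscape.overlap.pivot(
        index="county_id", columns="huc8_id", values="weight"
    ).to_numpy()
    colsum = w.sum(axis=0)
    colsum[colsum == 0] = 1.0
    rows = []
    members = landscape.fine_units.groupby("huc8_id")["huc12_id"]
    priority = {
        int(h): rng.permutation(g.to_numpy()) for h, g in members
    }
    for year in p.columns:
        target = (w * p[year].to_numpy()[:, None]).sum(axis=0) / colsum
        for h, pri in priority.items():
            jitter = int(rng.choice([-1, 0, 1], p=[0.15, 0.7, 0.15]))
            k = int(np.clip(round(target[h] * len(pri)) + jitter, 0, len(pri)))
            invaded = set(pri[:k])
            for u in pri:
                rows.append((int(u), int(year), int(u in invaded)))
    return (
        pd.DataFrame(rows, columns=["huc12_id", "year", "invaded"])
        .sort_values(["year", "huc12_id"], ignore_index=True)
    )


def _spatial_field(
    rng: np.random.Generator, x: np.ndarray, y: np.ndarray, n_waves: int = 4
) -> np.ndarray:
    """Smooth random surface on centroids: sum of low-frequency cosines."""
    span = max(x.max() - x.min(), y.max() - y.min(), 1.0)
    out = np.zeros_like(x, dtype=float)
    for _ in range(n_waves):
        kx, ky = rng.normal(0, 2 * np.pi / span, 2)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.normal(0, 1) * np.cos(kx * x + ky * y + phase)
    return out / math.sqrt(n_waves)


def make_covariates(
    landscape: Landscape, years: Sequence[int], seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate county-level and coarse-watershed-level covariates.

    Returns ``(county_covs, huc8_covs)``. County covariates are static
    habitat descriptors (habitat suitability, density, land-cover
    percentages) plus county-year removal effort; watershed covariates
    are the four static predictors used by the invasion model. All
    surfaces are spatially autocorrelated via smooth random fields.
    """
    years = list(years)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 303]))
    c = landscape.counties
    x, y = c["cx"].to_numpy(), c["cy"].to_numpy()

    def pct(f: np.ndarray) -> np.ndarray:
        return 100.0 / (1.0 + np.exp(-f))

    hsi = 1.0 / (1.0 + np.exp(-_spatial_field(rng, x, y)))
    county = pd.DataFrame(
        {
            "county_id": c["county_id"],
            "hsi": hsi,
            "density": np.exp(0.5 * _spatial_field(rng, x, y)),
            "pct_hydrology": pct(_spatial_field(rng, x, y) - 1.5),
            "pct_tree": pct(_spatial_field(rng, x, y)),
            "pct_crop": pct(_spatial_field(rng, x, y)),
            "pct_pasture": pct(_spatial_field(rng, x, y) - 0.5),
            "pct_deciduous": pct(_spatial_field(rng, x, y) - 0.8),
        }
    )

    rem_base = np.exp(_spatial_field(rng, x, y)) * 5.0
    rem_rows = []
    for year in years:
        lam = rem_base * rng.lognormal(-0.125, 0.5, len(x))
        rem_rows.append(
            pd.DataFrame(
                {
                    "county_id": c["county_id"],
                    "year": year,
                    "removals": rng.poisson(lam).astype(float),
                    "active_removal_prop": rng.beta(2, 5, len(x)) * hsi,
                }
            )
        )
    county_year = pd.concat(rem_rows, ignore_index=True)
    county_covs = county_year.merge(county, on="county_id")

    ws = landscape.watersheds
    wxy = (ws["cx"].to_numpy(), ws["cy"].to_numpy())
    huc8_covs = pd.DataFrame(
        {
            "huc8_id": ws["huc8_id"],
            "ruggedness": np.exp(0.6 * _spatial_field(rng, *wxy)),
            "lewis_density": np.exp(0.5 * _spatial_field(rng, *wxy)),
            "temp_range": 20.0 + 5.0 * _spatial_field(rng, *wxy),
            "precip": np.exp(6.5 + 0.4 * _spatial_field(rng, *wxy)),
        }
    )
    return county_covs, huc8_covs


DEFAULT_CATEGORIES: dict[str, list[tuple[str, str]]] = {
    "field_crops": [("corn", "acres"), ("soybeans", "acres"), ("wheat", "acres")],
    "grasses_hay": [("hay", "acres")],
    "pasture": [("pasture", "acres")],
    "wetlands": [("wetlands", "acres")],
    "livestock": [("cattle", "head"), ("hogs", "head")],
}


def make_resources(
    landscape: Landscape,
    categories: Mapping[str, list[tuple[str, str]]] | None = None,
    seed: int = 0,
):
    """Generate resource, price, yield, and cash-rent tables.

    ``categories`` maps category name -> list of (resource, unit). Land
    resources (unit == acres) are allocated so a county's total acreage
    never exceeds its area; at least one state is left without a cash
    rent so the national fallback is exercised. Returns a
    :class:`pigspread.valuation.ResourceLedger`.
    """
    from .valuation import ResourceLedger

    if categories is None:
        categories = DEFAULT_CATEGORIES
    if not categories:
        raise ValueError("at least one resource category required")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 404]))
    land = [
        (cat, res)
        for cat, lst in categories.items()
        for res, unit in lst
        if unit == "acres"
    ]
    heads = [
        (cat, res)
        for cat, lst in categories.items()
        for res, unit in lst
        if unit != "acres"
    ]

    rows = []
    for cid, area in landscape.areas.items():
        total_acres = km2_to_acres(area)
        if land:
            # Dirichlet with a slack component keeps sum < county area
            shares = rng.dirichlet(np.ones(len(land) + 1))[:-1]
            for (cat, res), s in zip(land, shares):
                rows.append((cid, cat, res, s * total_acres, "acres"))
        for cat, res in heads:
            rows.append((cid, cat, res, float(rng.poisson(2e4)), "head"))
    resources = pd.DataFrame(
        rows, columns=["county_id", "category", "resource", "amount", "unit"]
    )

    crop_res = sorted(
        {res for cat, lst in categories.items() for res, unit in lst
         if unit == "acres" and cat not in ("pasture", "wetlands")}
    )
    prices = pd.DataFrame(
        {"resource": crop_res,
         "price": rng.uniform(2.0, 12.0, len(crop_res))}
    )
    states = sorted(landscape.states.unique())
    yields = pd.DataFrame(
        [
            (s, res, rng.uniform(20.0, 180.0))
            for s in states
            for res in crop_res
        ],
        columns=["state_id", "resource", "yield_per_acre"],
    )
    # drop one state's rent to exercise the national fallback
    rented = states[:-1] if len(states) > 1 else []
    cash_rents = pd.DataFrame(
        {"state_id": rented,
         "rent_per_acre": rng.uniform(10.0, 60.0, len(rented))}
    )
    national_rent = float(rng.uniform(15.0, 40.0))
    return ResourceLedger(resources, prices, yields, cash_rents, national_rent)


INVASION_PREDICTORS = (
    "ruggedness",
    "lewis_density",
    "temp_range",
    "precip",
    "prev_rate",
    "distance",
)


def make_truth_scenario(
    landscape: Landscape,
    coefficients: Sequence[float] | Mapping[str, float],
    inv_beta: tuple[float, float] = (3.0, 12.0),
    ext_beta: tuple[float, float] = (1.5, 30.0),
    years: Sequence[int] = range(2004, 2013),
    seed: int = 0,
    *,
    intercept: float = 0.0,
    mode: str = "bernoulli",
    init_frac: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate fine-watershed invasion history from a known model.

    Each year every uninvaded fine unit has invasion probability
    ``expit(intercept + x . beta)`` over the six standard predictors:
    the four static watershed covariates plus the previous-year invaded
    rate of its coarse watershed and the distance from the coarse
    centroid to the nearest invaded fine unit. Dynamics are computed at
    the coarse level and shared by member fine units, matching how the
    fitted model predicts.

    mode="bernoulli" (default): units invade independently with that
    probability, so fitted coefficients are directly recoverable.
    mode="rate_constrained": the annual invasion count is
    round(rate x #uninvaded) with rate ~ Beta(inv_beta), and units are
    chosen by probability-weighted sampling without replacement — the
    simulator's own generative process. Extinctions follow ext_beta
    uniformly at random in both modes.

    Returns ``(huc8_covs, huc12_status, truth)``; all drawn annual rates
    are recorded on the truth object for recovery tests.
    """
    if isinstance(coefficients, Mapping):
        beta = pd.Series(
            {k: float(coefficients[k]) for k in INVASION_PREDICTORS}
        )
    else:
        if len(coefficients) != len(INVASION_PREDICTORS):
            raise ValueError(
                f"expected {len(INVASION_PREDICTORS)} coefficients, "
                f"got {len(coefficients)}"
            )
        beta = pd.Series(dict(zip(INVASION_PREDICTORS, map(float, coefficients))))
    if mode not in ("bernoulli", "rate_constrained"):
        raise ValueError(f"unknown mode {mode!r}")

    years = list(years)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 505]))
    _, huc8_covs = make_covariates(landscape, years, seed=seed)

    fine = landscape.fine_units.sort_values("huc12_id")
    n_fine = len(fine)
    f2c = fine["huc8_id"].to_numpy()
    fxy = fine[["cx", "cy"]].to_numpy()
    ws = landscape.watersheds.sort_values("huc8_id")
    wxy = ws[["cx", "cy"]].to_numpy()
    static_coarse = huc8_covs.set_index("huc8_id").loc[
        ws["huc8_id"], ["ruggedness", "lewis_density", "temp_range", "precip"]
    ].to_numpy()

    status = np.zeros(n_fine, dtype=bool)
    n_init = max(1, int(round(init_frac * n_fine)))
    status[rng.choice(n_fine, n_init, replace=False)] = True

    counts = np.bincount(f2c, minlength=len(ws))
    rows = []
    inv_draws, ext_draws = [], []
    year0 = years[0]
    rows.extend(
        (int(u), year0, int(s)) for u, s in zip(fine["huc12_id"], status)
    )
    for year in years[1:]:
        inv_count_per_coarse = np.bincount(f2c[status], minlength=len(ws))
        prev_rate = inv_count_per_coarse / np.maximum(counts, 1)
        dist = _nearest_invaded_distance(wxy, status, fine_xy=fxy)
        x = np.column_stack([static_coarse, prev_rate, dist])
        eta_coarse = intercept + x @ beta.to_numpy()
        prob = (1.0 / (1.0 + np.exp(-eta_coarse)))[f2c]

        uninv = np.flatnonzero(~status)
        if mode == "bernoulli":
            newly = uninv[rng.random(len(uninv)) < prob[uninv]]
        else:
            rate = rng.beta(*inv_beta)
            inv_draws.append(rate)
            k = min(int(round(rate * len(uninv))), len(uninv))
            newly = _weighted_sample(rng, uninv, prob[uninv], k)
        status[newly] = True

        invaded = np.flatnonzero(status)
        rate_e = rng.beta(*ext_beta)
        ext_draws.append(rate_e)
        k_e = min(int(round(rate_e * len(invaded))), len(invaded))
        if k_e:
            gone = rng.choice(invaded, k_e, replace=False)
            status[gone] = False
        rows.extend(
            (int(u), year, int(s)) for u, s in zip(fine["huc12_id"], status)
        )

    huc12 = pd.DataFrame(rows, columns=["huc12_id", "year", "invaded"])
    truth = SyntheticTruth(
        coefficients=beta,
        intercept=float(intercept),
        inv_beta=tuple(inv_beta),
        ext_beta=tuple(ext_beta),
        seed=seed,
        inv_rate_draws=np.asarray(inv_draws),
        ext_rate_draws=np.asarray(ext_draws),
    )
    return huc8_covs, huc12, truth


def _nearest_invaded_distance(
    points_xy: np.ndarray, status: np.ndarray, fine_xy: np.ndarray | None = None
) -> np.ndarray:
    """Euclidean distance from each point to the nearest invaded unit.

    ``status`` flags invaded units located at ``fine_xy`` (defaults to
    ``points_xy`` itself, in which case invaded units get exactly 0).
    With nothing invaded a large sentinel is returned for every point.
    """
    points_xy = np.asarray(points_xy, dtype=float)
    status = np.asarray(status, dtype=bool)
    same = fine_xy is None
    fine_xy = points_xy if same else np.asarray(fine_xy, dtype=float)
    if not status.any():
        span = np.hypot(*np.ptp(np.vstack([points_xy, fine_xy]), axis=0))
        return np.full(len(points_xy), span + 1.0)
    inv_xy = fine_xy[status]
    if same:
        out = np.zeros(len(points_xy))
        uninv = np.flatnonzero(~status)
        if len(uninv):
            d = np.hypot(
                points_xy[uninv, 0][:, None] - inv_xy[:, 0][None, :],
                points_xy[uninv, 1][:, None] - inv_xy[:, 1][None, :],
            )
            out[uninv] = d.min(axis=1)
        return out
    d = np.hypot(
        points_xy[:, 0][:, None] - inv_xy[:, 0][None, :],
        points_xy[:, 1][:, None] - inv_xy[:, 1][None, :],
    )
    return d.min(axis=1)


def _weighted_sample(
    rng: np.random.Generator, items: np.ndarray, weights: np.ndarray, k: int
) -> np.ndarray:
    """Probability-weighted sampling without replacement.

    Efraimidis–Spirakis exponential keys: equivalent to drawing items
    one at a time with probability proportional to weight among those
    remaining.
    """
    if k <= 0:
        return items[:0]
    if k >= len(items):
        return items
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative selection weight")
    if w.sum() <= 0:
        w = np.ones_like(w)
    keys = rng.exponential(1.0, len(items)) / np.where(w > 0, w, 1e-300)
    return items[np.argsort(keys, kind="stable")[:k]]


def write_landscape_csvs(landscape: Landscape, outdir) -> dict[str, str]:
    """Write the landscape tables as CSVs; returns name -> path."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, df in [
        ("counties", landscape.counties),
        ("adjacency", landscape.adjacency),
        ("watersheds", landscape.watersheds),
        ("fine_units", landscape.fine_units),
        ("overlap", landscape.overlap),
    ]:
        p = os.path.join(outdir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p
    return paths
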