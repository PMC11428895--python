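"""Watershed invasion-probability model and stochastic spread simulator.

Fine (12-digit-style) watersheds are treated as discrete populations
replicated within coarse (8-digit-style) watersheds. A logistic-binomial
model with six predictors — terrain ruggedness, predicted density,
annual temperature range, annual mean precipitation, previous-year
invaded rate, and distance to the nearest invaded watershed — gives
per-watershed invasion probabilities. The simulator draws annual
invasion and extinction rates from beta distributions fit to observed
rate series, assigns invasions by probability-weighted sampling without
replacement, applies extinctions uniformly at random, updates coarse
proportions and distances each year, and repeats over many independent
replicate streams.

Regional variation ("ri"/"rs" variants) is represented by four-region
intercept (and dynamic-slope) offsets estimated by maximum likelihood —
a fixed-effects stand-in for random effects; forecasting consumes only
the induced probability function, so the contract is unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .rates import watershed_response
from .synth import (
    INVASION_PREDICTORS,
    REGIONS,
    Landscape,
    _nearest_invaded_distance,
    _weighted_sample,
)

log = logging.getLogger(__name__)

VARIANTS = ("fixed", "ri", "rs")
#: dynamic predictors that get regional slopes under the "rs" variant
DYNAMIC_PREDICTORS = ("prev_rate", "distance")


class RateDraw(Protocol):
    """Annual rate source: anything with draw(rng) -> float in [0, 1]."""

    def draw(self, rng: np.random.Generator) -> float: ...


@dataclass(frozen=True)
class BetaRateDistribution:
    """Beta distribution over annual invasion or extinction rates."""

    alpha: float
    beta: float
    kind: str = "invasion"
    window: tuple[int, int] | None = None

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.alpha, self.beta))


def fit_beta_rates(
    series: pd.Series | Sequence[float],
    kind: str = "invasion",
    window: tuple[int, int] | None = None,
) -> BetaRateDistribution:
    """Method-of-moments beta fit to an annual rate series.

    With sample mean m and unbiased variance v:
    alpha = m(m(1−m)/v − 1), beta = (1−m)(m(1−m)/v − 1).
    Series containing exact 0s or 1s are shrunk toward the interior by
    r -> (r(n−1) + 0.5)/n before fitting so the moments stay valid.
    """
    r = np.asarray(pd.Series(series).dropna(), dtype=float)
    if len(r) < 2:
        raise ValueError("need at least 2 rates to fit a beta")
    if np.any((r < 0) | (r > 1)):
        raise ValueError("rates must lie in [0, 1]")
    n = len(r)
    if np.any((r <= 0) | (r >= 1)):
        r = (r * (n - 1) + 0.5) / n
    m = float(r.mean())
    v = float(r.var(ddof=1))
    if np.ptp(r) == 0 or v < 1e-12 * max(m * (1 - m), 1e-12):
        raise ValueError("zero-variance rate series; no beta fit")
    if v >= m * (1 - m):
        raise ValueError(
            f"variance {v:.4g} >= m(1-m) = {m * (1 - m):.4g}; no valid beta"
        )
    scale = m * (1 - m) / v - 1
    return BetaRateDistribution(m * scale, (1 - m) * scale, kind, window)


def nearest_invaded_distance(
    points_xy: np.ndarray, status: np.ndarray, fine_xy: np.ndarray | None = None
) -> np.ndarray:
    """Distance from each point to the nearest invaded fine unit.

    ``status`` flags invaded fine units whose centroids are ``fine_xy``
    (defaults to ``points_xy`` itself, in which case invaded units get
    exactly 0). With nothing invaded a large sentinel is returned.
    """
    return _nearest_invaded_distance(points_xy, status, fine_xy)


def dynamic_covariates(
    huc12_status: pd.DataFrame, landscape: Landscape
) -> pd.DataFrame:
    """Previous-year invaded rate and nearest-invaded distance per coarse unit.

    For each year t with data at t−1: prev_rate is the invaded fraction
    of member fine units at t−1 and distance is from the coarse centroid
    to the nearest invaded fine unit anywhere at t−1.
    """
    resp = watershed_response(huc12_status, landscape.fine_to_coarse())
    wide = resp.pivot(index="huc8_id", columns="year", values="rate").sort_index()
    fine = landscape.fine_units.sort_values("huc12_id")
    fxy = fine[["cx", "cy"]].to_numpy()
    wxy = landscape.watersheds.sort_values("huc8_id")[["cx", "cy"]].to_numpy()
    st = huc12_status.pivot(index="huc12_id", columns="year", values="invaded")
    st = st.loc[fine["huc12_id"]]

    years = sorted(st.columns)
    rows = []
    for prev, year in zip(years, years[1:]):
        status = st[prev].to_numpy().astype(bool)
        dist = nearest_invaded_distance(wxy, status, fxy)
        for i, h in enumerate(wide.index):
            rows.append((int(h), int(year), float(wide.loc[h, prev]), dist[i]))
    return pd.DataFrame(rows, columns=["huc8_id", "year", "prev_rate", "distance"])


def invasion_design(
    response: pd.DataFrame,
    huc8_covs: pd.DataFrame,
    dynamics: pd.DataFrame,
    landscape: Landscape,
) -> pd.DataFrame:
    """Join the binomial response with static + dynamic predictors."""
    d = response.merge(dynamics, on=["huc8_id", "year"])
    d = d.merge(huc8_covs, on="huc8_id")
    d = d.merge(landscape.watersheds[["huc8_id", "region"]], on="huc8_id")
    return d


@dataclass(frozen=True)
class InvasionModel:
    """Fitted logistic-binomial invasion-probability model."""

    variant: str
    params: pd.Series
    bse: pd.Series
    feature_names: tuple[str, ...]

    def coefficient_table(self) -> pd.DataFrame:
        return pd.DataFrame({"coef": self.params, "se": self.bse})

    def linear_predictor(self, covariates: pd.DataFrame) -> np.ndarray:
        X = _exog(covariates, self.variant)
        X = X.reindex(columns=self.feature_names, fill_value=0.0)
        return X.to_numpy() @ self.params.reindex(self.feature_names).to_numpy()

    def predict_prob(self, covariates: pd.DataFrame) -> np.ndarray:
        """Invasion probability per row; strictly inside (0, 1)."""
        p = expit(self.linear_predictor(covariates))
        return np.clip(p, 1e-12, 1 - 1e-12)


def _exog(df: pd.DataFrame, variant: str) -> pd.DataFrame:
    missing = [c for c in INVASION_PREDICTORS if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariate column(s): {missing}")
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    for c in INVASION_PREDICTORS:
        X[c] = df[c].astype(float)
    if variant in ("ri", "rs"):
        if "region" not in df.columns:
            raise ValueError("missing covariate column(s): ['region']")
        # baseline region is REGIONS[0]; offsets for the other three
        for r in REGIONS[1:]:
            X[f"region[{r}]"] = (df["region"] == r).astype(float)
        if variant == "rs":
            for r in REGIONS[1:]:
                for c in DYNAMIC_PREDICTORS:
                    X[f"region[{r}]:{c}"] = X[f"region[{r}]"] * X[c]
    return X


def fit_invasion_model(
    design: pd.DataFrame, variant: str = "fixed"
) -> InvasionModel:
    """Fit the six-predictor binomial invasion model by maximum likelihood.

    ``design`` needs k, n, the six predictors, and a region column for
    the regional variants. Raises on an all-invaded/all-uninvaded
    response or on complete separation.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    if {"k", "n"} - set(design.columns):
        raise ValueError("design must carry binomial response columns k, n")
    k = design["k"].to_numpy(float)
    n = design["n"].to_numpy(float)
    if np.all(k == 0):
        raise ValueError("response is all-uninvaded; model not identifiable")
    if np.all(k == n):
        raise ValueError("response is all-invaded; model not identifiable")

    X = _exog(design, variant)
    endog = np.column_stack([k, n - k])
    try:
        res = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial()).fit()
    except Exception as exc:  # statsmodels raises several separation types
        raise ValueError(
            f"invasion model fit failed ({exc}); data may be separable — "
            "consider regularization or more data"
        ) from exc
    if not np.all(np.isfinite(res.params)):
        raise ValueError(
            "non-finite coefficients: complete separation suspected — "
            "consider regularization"
        )
    names = tuple(X.columns)
    return InvasionModel(
        variant=variant,
        params=pd.Series(res.params, index=names),
        bse=pd.Series(res.bse, index=names),
        feature_names=names,
    )


def predict_invasion_prob(
    model: InvasionModel,
    huc8_covs: pd.DataFrame,
    landscape: Landscape,
    status: pd.Series,
) -> pd.Series:
    """Invasion probability for every currently uninvaded fine watershed.

    Dynamic covariates (previous-year invaded rate and nearest-invaded
    distance) are computed from ``status`` at the coarse level and the
    coarse probability is shared by member fine units.
    """
    fine = landscape.fine_units.sort_values("huc12_id")
    st = status.reindex(fine["huc12_id"]).astype(bool)
    if st.isna().any():
        raise ValueError("status missing fine watersheds")
    probs = _coarse_probs(model, huc8_covs, landscape, st.to_numpy())
    f2c = fine["huc8_id"].to_numpy()
    per_fine = pd.Series(probs[f2c], index=fine["huc12_id"])
    return per_fine[~st.to_numpy()]


class _CoarseProbEvaluator:
    """Fast per-year coarse invasion probabilities for a fixed model.

    The static part of the linear predictor (intercept, the four static
    covariates, regional offsets) is precomputed; each call only folds
    in the dynamic previous-rate and distance terms, including regional
    slope interactions.
    """

    def __init__(self, model: InvasionModel, huc8_covs: pd.DataFrame,
                 landscape: Landscape):
        ws = landscape.watersheds.sort_values("huc8_id")
        fine = landscape.fine_units.sort_values("huc12_id")
        self.f2c = fine["huc8_id"].to_numpy()
        self.fine_xy = fine[["cx", "cy"]].to_numpy()
        self.coarse_xy = ws[["cx", "cy"]].to_numpy()
        self.n_coarse = len(ws)
        self.counts = np.bincount(self.f2c, minlength=self.n_coarse)

        cov = pd.DataFrame(
            {c: 0.0 for c in DYNAMIC_PREDICTORS},
            index=range(self.n_coarse),
        )
        stat = huc8_covs.set_index("huc8_id").loc[ws["huc8_id"]]
        for c in ("ruggedness", "lewis_density", "temp_range", "precip"):
            cov[c] = stat[c].to_numpy()
        cov["region"] = ws["region"].to_numpy()
        self.eta_static = model.linear_predictor(cov)

        p = model.params
        region = ws["region"].to_numpy()
        self.coef_dyn = {}
        for c in DYNAMIC_PREDICTORS:
            coefs = np.full(self.n_coarse, float(p.get(c, 0.0)))
            for r in REGIONS[1:]:
                key = f"region[{r}]:{c}"
                if key in p.index:
                    coefs[region == r] += float(p[key])
            self.coef_dyn[c] = coefs

    def __call__(self, status: np.ndarray) -> np.ndarray:
        inv_counts = np.bincount(self.f2c[status], minlength=self.n_coarse)
        prev_rate = inv_counts / np.maximum(self.counts, 1)
        dist = _nearest_invaded_distance(self.coarse_xy, status, self.fine_xy)
        eta = (
            self.eta_static
            + self.coef_dyn["prev_rate"] * prev_rate
            + self.coef_dyn["distance"] * dist
        )
        return np.clip(expit(eta), 1e-12, 1 - 1e-12)


def _coarse_probs(
    model: InvasionModel,
    huc8_covs: pd.DataFrame,
    landscape: Landscape,
    status: np.ndarray,
) -> np.ndarray:
    return _CoarseProbEvaluator(model, huc8_covs, landscape)(status)


@dataclass(frozen=True)
class SimulationResult:
    """Replicate trajectories from the stochastic invasion simulator."""

    years: tuple[int, ...]
    fine_ids: np.ndarray
    coarse_ids: np.ndarray
    fine_status: np.ndarray      # (reps, horizon, n_fine) bool
    coarse_props: np.ndarray     # (reps, horizon, n_coarse)
    invasion_counts: np.ndarray  # (reps, horizon)
    extinction_counts: np.ndarray

    @property
    def reps(self) -> int:
        return self.fine_status.shape[0]


def simulate(
    model: InvasionModel,
    landscape: Landscape,
    huc8_covs: pd.DataFrame,
    initial_status: pd.Series,
    inv_rate: RateDraw,
    ext_rate: RateDraw,
    horizon: int = 8,
    reps: int = 1000,
    seed: int = 0,
    start_year: int = 2013,
    count_denominator: str = "current",
) -> SimulationResult:
    """Run the stochastic invasion/extinction simulation.

    Per replicate and year: draw an invasion rate, convert it to a count
    (rate × currently uninvaded units by default, × total units with
    ``count_denominator="total"``), assign that many uninvaded units as
    invaded by probability-weighted sampling without replacement, draw
    an extinction rate and remove the corresponding count uniformly at
    random among units invaded at the start of the year, then update
    coarse proportions and distances. Each replicate runs on an
    independent child stream of ``seed``; counts exceeding the available
    units are capped with a logged note.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if count_denominator not in ("current", "total"):
        raise ValueError(f"unknown count_denominator {count_denominator!r}")

    fine = landscape.fine_units.sort_values("huc12_id")
    fine_ids = fine["huc12_id"].to_numpy()
    f2c = fine["huc8_id"].to_numpy()
    n_fine = len(fine_ids)
    n_coarse = len(landscape.watersheds)
    counts = np.bincount(f2c, minlength=n_coarse)
    init = initial_status.reindex(fine_ids).astype(bool).to_numpy()

    years = tuple(start_year + s for s in range(1, horizon + 1))
    fine_status = np.zeros((reps, horizon, n_fine), dtype=bool)
    coarse_props = np.zeros((reps, horizon, n_coarse))
    inv_counts = np.zeros((reps, horizon), dtype=int)
    ext_counts = np.zeros((reps, horizon), dtype=int)

    evaluator = _CoarseProbEvaluator(model, huc8_covs, landscape)
    streams = np.random.SeedSequence(seed).spawn(reps)
    capped = 0
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        status = init.copy()
        for t in range(horizon):
            n_invaded_start = int(status.sum())
            uninv = np.flatnonzero(~status)
            invaded = np.flatnonzero(status)

            probs = evaluator(status)
            weights = probs[f2c[uninv]]

            r_inv = float(inv_rate.draw(rng))
            base_inv = len(uninv) if count_denominator == "current" else n_fine
            k_inv = int(round(r_inv * base_inv))
            if k_inv > len(uninv):
                capped += 1
                k_inv = len(uninv)
            newly = _weighted_sample(rng, uninv, weights, k_inv)

            r_ext = float(ext_rate.draw(rng))
            base_ext = len(invaded) if count_denominator == "current" else n_fine
            k_ext = int(round(r_ext * base_ext))
            if k_ext > len(invaded):
                capped += 1
                k_ext = len(invaded)
            gone = (
                rng.choice(invaded, k_ext, replace=False)
                if k_ext
                else invaded[:0]
            )

            status[newly] = True
            status[gone] = False
            # conservation: invaded(t+1) = invaded(t) + invasions - extinctions
            assert int(status.sum()) == n_invaded_start + len(newly) - len(gone)

            fine_status[r, t] = status
            coarse_props[r, t] = (
                np.bincount(f2c[status], minlength=n_coarse)
                / np.maximum(counts, 1)
            )
            inv_counts[r, t] = len(newly)
            ext_counts[r, t] = len(gone)
    if capped:
        log.info("capped %d drawn counts at the available unit pool", capped)

    return SimulationResult(
        years=years,
        fine_ids=fine_ids,
        coarse_ids=landscape.watersheds.sort_values("huc8_id")["huc8_id"].to_numpy(),
        fine_status=fine_status,
        coarse_props=coarse_props,
        invasion_counts=inv_counts,
        extinction_counts=ext_counts,
    )


def summarize(result: SimulationResult) -> pd.DataFrame:
    """Median and 2.5/97.5-percentile invaded proportion per coarse unit-year."""
    med = np.median(result.coarse_props, axis=0)
    lo = np.percentile(result.coarse_props, 2.5, axis=0)
    hi = np.percentile(result.coarse_props, 97.5, axis=0)
    rows = []
    for t, year in enumerate(result.years):
        for i, h in enumerate(result.coarse_ids):
            rows.append((int(h), year, med[t, i], lo[t, i], hi[t, i]))
    return pd.DataFrame(
        rows, columns=["huc8_id", "year", "median", "lo95", "hi95"]
    )


def to_county(
    coarse_props: pd.DataFrame, overlap: pd.DataFrame, value_col: str = "median"
) -> pd.DataFrame:
    """Map coarse-watershed proportions to counties via overlap weights.

    county proportion = sum over watersheds of weight × proportion.
    Weights must sum to 1 per county.
    """
    wsum = overlap.groupby("county_id")["weight"].sum()
    bad = wsum[(wsum - 1).abs() > 1e-6]
    if len(bad):
        raise ValueError(
            f"overlap weights not normalized for counties {list(bad.index[:5])}"
        )
    m = overlap.merge(coarse_props, on="huc8_id")
    m["contrib"] = m["weight"] * m[value_col]
    out = (
        m.groupby(["county_id", "year"], as_index=False)["contrib"]
        .sum()
        .rename(columns={"contrib": "prop"})
    )
    return out
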