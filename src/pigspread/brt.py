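"""Least-squares boosted-tree spread models and step-ahead forecasting.

Four model variants (A–D) are fit to per-county pre-program mean spread
rates, separately for the persistent and transient strata, then rolled
forward deterministically one year at a time for the forecast horizon.
Predicted deltas are added to the current occupancy, bounded to the
valid range, and the adjacent-occupancy covariate is recomputed from the
updated map before the next step.

The boosting backend is scikit-learn's gradient boosting with squared
loss, which is stage-wise least-squares fitting of shallow regression
trees with shrinkage: the initial prediction is the response mean and
each tree fits the current residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor

from .synth import Landscape

log = logging.getLogger(__name__)

STATIC_FEATURES = (
    "hsi",
    "density",
    "pct_hydrology",
    "pct_tree",
    "pct_crop",
    "pct_pasture",
    "pct_deciduous",
)


class Predictor(Protocol):
    """Anything mapping a feature frame to per-row delta predictions."""

    def predict(self, X: pd.DataFrame) -> np.ndarray: ...


@dataclass(frozen=True)
class SpreadModelSpec:
    """One of the four response/covariate configurations.

    A: proportion deltas, with previous focal status.
    B: proportion deltas, without it.
    C: km² deltas, with previous focal status.
    D: km² deltas, without it.
    """

    model_id: str
    response_scale: str          # "proportion" | "km2"
    include_previous_status: bool

    @classmethod
    def from_id(cls, model_id: str) -> "SpreadModelSpec":
        m = model_id.upper()
        table = {
            "A": ("proportion", True),
            "B": ("proportion", False),
            "C": ("km2", True),
            "D": ("km2", False),
        }
        if m not in table:
            raise ValueError(f"unknown model id {model_id!r}")
        scale, prev = table[m]
        return cls(m, scale, prev)

    def feature_names(self) -> list[str]:
        names = []
        if self.include_previous_status:
            names.append(
                "prev_prop" if self.response_scale == "proportion" else "prev_km2"
            )
        names.append("adj_mean_prop")
        names.append(
            "removals_per_km2_prev"
            if self.response_scale == "proportion"
            else "removals_sum_prev"
        )
        names += [
            "adj_mean_removals_log",
            "active_removal_prop_prev",
            "adj_active_removal_prev",
            *STATIC_FEATURES,
        ]
        return names


@dataclass
class BoostedEnsemble:
    """Stage-wise least-squares boosted trees with shrinkage.

    prediction(x) = init + shrinkage * sum of tree outputs; the training
    MSE path over boosting rounds is recorded and non-increasing.
    """

    model: GradientBoostingRegressor
    feature_names: list[str]
    init_prediction: float
    train_mse_path: np.ndarray
    importances: pd.Series
    shrinkage: float
    n_rounds: int
    max_depth: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict(np.asarray(X[self.feature_names], dtype=float))


def fit_lsboost(
    X: pd.DataFrame,
    y: Sequence[float],
    max_depth: int = 3,
    n_rounds: int = 500,
    shrinkage: float = 0.05,
    min_leaf: int = 5,
    seed: int = 0,
) -> BoostedEnsemble:
    """Fit a least-squares boosted tree ensemble.

    Stage 0 predicts the response mean; tree m fits the residuals left
    after m−1 rounds and is added with learning rate ``shrinkage``.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y):
        raise ValueError("features and response misaligned")
    if len(y) < 2:
        raise ValueError("need at least 2 observations")
    if not (0 < shrinkage <= 1):
        raise ValueError("shrinkage must be in (0, 1]")

    Xa = np.asarray(X, dtype=float)
    if np.ptp(Xa, axis=0).max(initial=0.0) == 0 and np.ptp(y) > 0:
        log.warning(
            "all features constant with non-constant response; "
            "fit degenerates to the response mean"
        )
    gbr = GradientBoostingRegressor(
        loss="squared_error",
        n_estimators=n_rounds,
        learning_rate=shrinkage,
        max_depth=max_depth,
        min_samples_leaf=min_leaf,
        random_state=seed,
    )
    gbr.fit(Xa, y)
    mse_path = np.array(
        [np.mean((y - pred) ** 2) for pred in gbr.staged_predict(Xa)]
    )
    return BoostedEnsemble(
        model=gbr,
        feature_names=list(X.columns),
        init_prediction=float(np.mean(y)),
        train_mse_path=mse_path,
        importances=pd.Series(gbr.feature_importances_, index=list(X.columns)),
        shrinkage=shrinkage,
        n_rounds=n_rounds,
        max_depth=max_depth,
    )


def _adjacency_lists(landscape: Landscape) -> dict[int, list[int]]:
    return landscape.neighbors()


def _neighbor_mean(values: pd.Series, neighbors: Mapping[int, list[int]]) -> pd.Series:
    """Mean of ``values`` over each county's neighbors (0 if isolated)."""
    out = {}
    for c, nbrs in neighbors.items():
        out[c] = float(values.loc[nbrs].mean()) if nbrs else 0.0
    return pd.Series(out).reindex(values.index)


def make_features(
    prop: pd.Series,
    removals: pd.Series,
    active_removal: pd.Series,
    static: pd.DataFrame,
    landscape: Landscape,
    spec: SpreadModelSpec,
) -> pd.DataFrame:
    """Assemble the covariate frame for one prediction step.

    All dynamic inputs are previous-year values indexed by county_id;
    ``static`` is indexed by county_id with the standard habitat and
    land-cover columns.
    """
    ids = landscape.county_ids
    areas = landscape.areas
    nbrs = _adjacency_lists(landscape)
    prop = prop.reindex(ids)
    removals = removals.reindex(ids).fillna(0.0)
    active_removal = active_removal.reindex(ids).fillna(0.0)

    X = pd.DataFrame(index=pd.Index(ids, name="county_id"))
    if spec.include_previous_status:
        if spec.response_scale == "proportion":
            X["prev_prop"] = prop
        else:
            X["prev_km2"] = prop * areas
    X["adj_mean_prop"] = _neighbor_mean(prop, nbrs)
    if spec.response_scale == "proportion":
        X["removals_per_km2_prev"] = removals / areas
    else:
        X["removals_sum_prev"] = removals
    X["adj_mean_removals_log"] = np.log1p(_neighbor_mean(removals, nbrs))
    X["active_removal_prop_prev"] = active_removal
    X["adj_active_removal_prev"] = _neighbor_mean(active_removal, nbrs)
    for col in STATIC_FEATURES:
        X[col] = static[col].reindex(ids).to_numpy()
    return X[spec.feature_names()]


def training_design(
    history: pd.DataFrame,
    covariates: pd.DataFrame,
    landscape: Landscape,
    spec: SpreadModelSpec,
    window: Sequence[int],
) -> pd.DataFrame:
    """Per-county training features for the pre-program mean-rate fit.

    Dynamic covariates (focal status, adjacent occupancy, removals) are
    averaged over the previous-year set {t−1 : t in window}, matching
    the response being a mean of annual deltas over the window.
    """
    window = list(window)
    prev_years = [t - 1 for t in window]
    p = history.pivot(index="county_id", columns="year", values="prop_occupied")
    missing = sorted(set(prev_years) - set(p.columns))
    if missing:
        raise ValueError(f"history missing years {missing}")
    prop = p[prev_years].mean(axis=1)

    cv = covariates[covariates["year"].isin(prev_years)]
    rem = cv.groupby("county_id")["removals"].mean()
    act = cv.groupby("county_id")["active_removal_prop"].mean()
    static = (
        covariates.drop_duplicates("county_id")
        .set_index("county_id")[list(STATIC_FEATURES)]
    )
    return make_features(prop, rem, act, static, landscape, spec)


def fit_spread_models(
    X: pd.DataFrame,
    response: pd.Series,
    strata: Mapping[str, set[int]],
    min_rows: int = 10,
    seed: int = 0,
    **boost_kw,
) -> dict[str, BoostedEnsemble]:
    """Fit independent persistent and transient ensembles.

    ``X`` and ``response`` are indexed by county_id; the two ensembles
    share the covariate manifest but are fit on disjoint strata.
    """
    out = {}
    for name in ("persistent", "transient"):
        ids = sorted(strata[name] & set(X.index) & set(response.index))
        if len(ids) < min_rows:
            raise ValueError(
                f"stratum {name!r} has {len(ids)} rows (< {min_rows})"
            )
        out[name] = fit_lsboost(
            X.loc[ids], response.loc[ids].to_numpy(), seed=seed, **boost_kw
        )
    return out


@dataclass(frozen=True)
class ForecastResult:
    """Deterministic step-ahead forecast output for one model."""

    model_id: str
    values: pd.DataFrame                     # county_id, year, prop, km2
    newly_occupied: dict[int, frozenset]     # year -> county ids
    newly_unoccupied: dict[int, frozenset]

    def occupancy(self) -> pd.DataFrame:
        """(county_id, year, prop) frame for downstream valuation."""
        return self.values[["county_id", "year", "prop"]].copy()


def step_ahead(
    models: Mapping[str, Predictor],
    state0: pd.Series,
    covariates: pd.DataFrame,
    landscape: Landscape,
    spec: SpreadModelSpec,
    strata: Mapping[str, set[int]],
    horizon: int = 8,
    tau: float = 0.0,
    start_year: int = 2013,
    noise_sd: float | None = None,
    removal_model: "BoostedEnsemble | None" = None,
    seed: int = 0,
) -> ForecastResult:
    """Iterate the fitted delta models forward ``horizon`` years.

    ``state0`` is the proportion occupied per county in ``start_year``;
    ``covariates`` provides the last observed removals/active-removal
    values (at ``start_year``) plus the static columns. Each year the
    stratum model predicts a delta on the spec's scale, the delta is
    added and clipped to [0, 1] (proportion) or [0, area] (km²), tau
    crossings are recorded, and the adjacent-occupancy covariate is
    recomputed from the updated map. Non-occupancy covariates are held
    at their last observed values unless a removal model is supplied,
    in which case removal covariates are refreshed from its predictions
    each step. ``noise_sd`` optionally adds seeded Gaussian noise to the
    deltas (off by default; the headline forecasts are deterministic).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    ids = landscape.county_ids
    areas = landscape.areas
    rng = np.random.default_rng(seed)

    assign = {}
    for c in ids:
        c = int(c)
        if c in strata["persistent"]:
            assign[c] = "persistent"
        else:
            # transient counties, and never-occupied ones, use the
            # transient model (closest analogue for new invasions)
            assign[c] = "transient"
    groups = {
        name: [c for c in ids if assign[int(c)] == name]
        for name in ("persistent", "transient")
    }

    static = (
        covariates.drop_duplicates("county_id")
        .set_index("county_id")[list(STATIC_FEATURES)]
    )
    last = covariates[covariates["year"] == start_year]
    if last.empty:
        last = covariates[covariates["year"] == covariates["year"].max()]
    removals = last.set_index("county_id")["removals"].reindex(ids).fillna(0.0)
    active = (
        last.set_index("county_id")["active_removal_prop"].reindex(ids).fillna(0.0)
    )

    prop = state0.reindex(ids).astype(float)
    if prop.isna().any():
        raise ValueError("state0 missing counties")
    km2 = prop * areas

    rows = []
    newly_occ: dict[int, frozenset] = {}
    newly_unocc: dict[int, frozenset] = {}
    for step in range(1, horizon + 1):
        year = start_year + step
        X = make_features(prop, removals, active, static, landscape, spec)
        delta = pd.Series(0.0, index=X.index)
        for name, members in groups.items():
            if members:
                delta.loc[members] = models[name].predict(X.loc[members])
        if noise_sd is not None:
            delta = delta + rng.normal(0.0, noise_sd, len(delta))

        if spec.response_scale == "proportion":
            new_prop = np.clip(prop + delta, 0.0, 1.0)
            new_km2 = new_prop * areas
        else:
            new_km2 = np.clip(km2 + delta, 0.0, areas)
            new_prop = new_km2 / areas

        up = prop.index[(prop <= tau) & (new_prop > tau)]
        down = prop.index[(prop > tau) & (new_prop <= tau)]
        newly_occ[year] = frozenset(int(c) for c in up)
        newly_unocc[year] = frozenset(int(c) for c in down)

        prop, km2 = pd.Series(new_prop, index=prop.index), pd.Series(
            new_km2, index=prop.index
        )
        if removal_model is not None:
            removals = update_removals(
                removal_model, prop, km2, removals, static, landscape
            )
        for c in ids:
            rows.append((int(c), year, float(prop.loc[c]), float(km2.loc[c])))

    values = pd.DataFrame(rows, columns=["county_id", "year", "prop", "km2"])
    return ForecastResult(spec.model_id, values, newly_occ, newly_unocc)


REMOVAL_FEATURES = ("km2_occupied", "removals_prev", "adj_mean_removals_prev") + (
    STATIC_FEATURES
)


def fit_removal_model(
    covariates: pd.DataFrame,
    history: pd.DataFrame,
    landscape: Landscape,
    window: Sequence[int],
    seed: int = 0,
    **boost_kw,
) -> BoostedEnsemble:
    """Model removal effort from occupancy and habitat covariates.

    Response: removals in the focal county in year t. Features: current
    km² occupied, previous-year removals (focal and adjacent mean), and
    the static habitat/land-cover covariates. Fit on all counties
    pooled (no strata).
    """
    nbrs = _adjacency_lists(landscape)
    areas = landscape.areas
    p = history.pivot(index="county_id", columns="year", values="prop_occupied")
    rem = covariates.pivot(index="county_id", columns="year", values="removals")
    static = (
        covariates.drop_duplicates("county_id")
        .set_index("county_id")[list(STATIC_FEATURES)]
    )
    frames, ys = [], []
    for t in window:
        if t not in rem.columns or (t - 1) not in rem.columns:
            continue
        X = pd.DataFrame(index=p.index)
        X["km2_occupied"] = p[t] * areas
        X["removals_prev"] = rem[t - 1]
        X["adj_mean_removals_prev"] = _neighbor_mean(rem[t - 1], nbrs)
        for col in STATIC_FEATURES:
            X[col] = static[col]
        frames.append(X)
        ys.append(rem[t])
    Xall = pd.concat(frames)
    yall = pd.concat(ys).to_numpy()
    return fit_lsboost(Xall, yall, seed=seed, **boost_kw)


def update_removals(
    model: BoostedEnsemble,
    prop: pd.Series,
    km2: pd.Series,
    removals_prev: pd.Series,
    static: pd.DataFrame,
    landscape: Landscape,
) -> pd.Series:
    """Refresh the removal covariate from the fitted removal model."""
    nbrs = _adjacency_lists(landscape)
    X = pd.DataFrame(index=km2.index)
    X["km2_occupied"] = km2
    X["removals_prev"] = removals_prev
    X["adj_mean_removals_prev"] = _neighbor_mean(removals_prev, nbrs)
    for col in STATIC_FEATURES:
        X[col] = static[col].reindex(km2.index).to_numpy()
    pred = model.predict(X)
    return pd.Series(np.clip(pred, 0.0, None), index=km2.index)


def forecast_transition_rates(result: ForecastResult) -> pd.DataFrame:
    """Per-year newly occupied/unoccupied counts with cumulative totals."""
    years = sorted(result.newly_occupied)
    df = pd.DataFrame(
        {
            "year": years,
            "newly_occupied": [len(result.newly_occupied[y]) for y in years],
            "newly_unoccupied": [len(result.newly_unoccupied[y]) for y in years],
        }
    )
    df["cum_occupied"] = df["newly_occupied"].cumsum()
    df["cum_unoccupied"] = df["newly_unoccupied"].cumsum()
    return df
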