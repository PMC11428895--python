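"""End-to-end orchestration: generate → prepare → fit → forecast → value.

Runs the full eight-model ensemble (BRT variants A–D plus four
stochastic occupancy parameterizations) on a synthetic landscape and
writes every stage output as CSV, with a checksum manifest and a config
echo for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import brt, occsim, rates, synth, valuation

log = logging.getLogger(__name__)

#: fourth occupancy parameterization: the fixed-effects model simulated
#: with the per-total-unit count conversion (config-switch variant)
OCC_MODELS = (
    ("occ_fixed", "fixed", "current"),
    ("occ_ri", "ri", "current"),
    ("occ_rs", "rs", "current"),
    ("occ_fixed_total", "fixed", "total"),
)


@dataclass
class RunConfig:
    """All knobs for a full pipeline run."""

    seed: int = 0
    out_dir: str = "pigspread_out"
    horizon: int = 8
    reps: int = 1000
    tau: float = 0.0

    n_counties: int = 100
    n_coarse: int = 12
    fine_per_coarse: int = 8
    n_states: int = 4
    persistent_frac: float = 0.29
    transient_frac: float = 0.40

    first_year: int = 2004
    last_year: int = 2021
    forecast_start: int = 2013
    pre_window: tuple[int, int] = (2009, 2013)
    rate_window: tuple[int, int] = (2004, 2012)

    brt_models: tuple[str, ...] = ("A", "B", "C", "D")
    occ_variants: tuple[str, ...] = tuple(m[0] for m in OCC_MODELS)
    max_depth: int = 3
    n_rounds: int = 500
    shrinkage: float = 0.05
    min_leaf: int = 5
    min_stratum_rows: int = 10
    removal_updates: bool = False
    noise: bool = False

    def __post_init__(self):
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        all_ids = list(self.brt_models) + list(self.occ_variants)
        if len(set(all_ids)) != len(all_ids):
            raise ValueError("model ids must be unique")
        known = {m[0] for m in OCC_MODELS}
        bad = set(self.occ_variants) - known
        if bad:
            raise ValueError(f"unknown occupancy variants {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("pre_window", "rate_window", "brt_models", "occ_variants"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _years(cfg: RunConfig) -> list[int]:
    return list(range(cfg.first_year, cfg.last_year + 1))


def generate_inputs(cfg: RunConfig):
    """Stage 1: synthetic landscape, history, covariates, resources."""
    landscape = synth.make_landscape(
        cfg.n_counties, cfg.n_coarse, cfg.fine_per_coarse,
        seed=cfg.seed, n_states=cfg.n_states,
    )
    occupancy, huc12 = synth.make_history(
        landscape, _years(cfg),
        persistent_frac=cfg.persistent_frac,
        transient_frac=cfg.transient_frac,
        seed=cfg.seed,
        # concentrate transient toggles inside the stratification window
        invasion_years=range(cfg.pre_window[0] + 1, cfg.pre_window[1] + 1),
    )
    covariates, huc8_covs = synth.make_covariates(landscape, _years(cfg), seed=cfg.seed)
    ledger = synth.make_resources(landscape, seed=cfg.seed)
    return landscape, occupancy, huc12, covariates, huc8_covs, ledger


def run_brt_model(
    model_id: str,
    landscape,
    occupancy: pd.DataFrame,
    covariates: pd.DataFrame,
    strata,
    cfg: RunConfig,
) -> tuple[brt.ForecastResult, dict[str, brt.BoostedEnsemble]]:
    """Fit one A–D variant on pre-program mean rates and roll it forward."""
    spec = brt.SpreadModelSpec.from_id(model_id)
    window = list(range(cfg.pre_window[0], cfg.pre_window[1] + 1))
    deltas = rates.annual_deltas(occupancy, landscape.areas)
    means = rates.preprogram_mean(deltas, window).set_index("county_id")
    response = (
        means["mean_dprop"] if spec.response_scale == "proportion"
        else means["mean_dkm2"]
    )
    X = brt.training_design(occupancy, covariates, landscape, spec, window)
    models = brt.fit_spread_models(
        X, response, strata,
        min_rows=cfg.min_stratum_rows, seed=cfg.seed,
        max_depth=cfg.max_depth, n_rounds=cfg.n_rounds,
        shrinkage=cfg.shrinkage, min_leaf=cfg.min_leaf,
    )
    state0 = (
        occupancy[occupancy["year"] == cfg.forecast_start]
        .set_index("county_id")["prop_occupied"]
    )
    removal_model = None
    if cfg.removal_updates:
        removal_model = brt.fit_removal_model(
            covariates, occupancy, landscape, window, seed=cfg.seed,
            max_depth=cfg.max_depth, n_rounds=cfg.n_rounds,
            shrinkage=cfg.shrinkage, min_leaf=cfg.min_leaf,
        )
    noise_sd = float(response.std()) if cfg.noise else None
    result = brt.step_ahead(
        models, state0, covariates, landscape, spec, strata,
        horizon=cfg.horizon, tau=cfg.tau, start_year=cfg.forecast_start,
        noise_sd=noise_sd, removal_model=removal_model, seed=cfg.seed,
    )
    return result, models


def run_occ_models(
    landscape, huc12: pd.DataFrame, huc8_covs: pd.DataFrame, cfg: RunConfig
) -> dict[str, pd.DataFrame]:
    """Fit the invasion model variants and simulate each to the horizon.

    Returns model id -> county proportion frame (county_id, year, prop)
    from the median replicate summary.
    """
    lo, hi = cfg.rate_window
    inv_series, ext_series = rates.observed_rates(huc12, range(lo, hi + 1))
    inv_beta = occsim.fit_beta_rates(inv_series, "invasion", (lo, hi))
    ext_beta = occsim.fit_beta_rates(ext_series, "extinction", (lo, hi))

    resp = rates.watershed_response(huc12, landscape.fine_to_coarse())
    dyn = occsim.dynamic_covariates(huc12, landscape)
    fit_years = [y for y in dyn["year"].unique() if y <= cfg.forecast_start]
    design = occsim.invasion_design(
        resp[resp["year"].isin(fit_years)], huc8_covs,
        dyn[dyn["year"].isin(fit_years)], landscape,
    )
    status0 = (
        huc12[huc12["year"] == cfg.forecast_start]
        .set_index("huc12_id")["invaded"].astype(bool)
    )

    out = {}
    wanted = {m[0]: m for m in OCC_MODELS if m[0] in cfg.occ_variants}
    for name, (_, variant, denom) in wanted.items():
        model = occsim.fit_invasion_model(design, variant)
        sim = occsim.simulate(
            model, landscape, huc8_covs, status0,
            inv_beta, ext_beta,
            horizon=cfg.horizon, reps=cfg.reps, seed=cfg.seed,
            start_year=cfg.forecast_start, count_denominator=denom,
        )
        med = occsim.summarize(sim)
        out[name] = occsim.to_county(med, landscape.overlap)
    return out


def _observed_forecast_window(occupancy: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    obs = occupancy[
        (occupancy["year"] > cfg.forecast_start)
        & (occupancy["year"] <= cfg.forecast_start + cfg.horizon)
    ]
    return obs.rename(columns={"prop_occupied": "prop"})[
        ["county_id", "year", "prop"]
    ]


def value_model(
    forecast: pd.DataFrame,
    observed: pd.DataFrame,
    ledger: valuation.ResourceLedger,
    landscape,
    model_id: str,
):
    """Stage 5 for one model: safeguarded amounts, dollars, metrics."""
    safeguarded = valuation.incremental_occupancy(forecast, observed)
    amounts = valuation.threatened_amount(safeguarded, ledger.resources)
    values = valuation.per_acre_value(ledger)
    summary = valuation.value_safeguarded(
        amounts, values, landscape.states, model=model_id
    )
    metrics = valuation.summary_metrics(summary)
    n_counties = int(
        safeguarded.loc[safeguarded["safeguarded_prop"] > 0, "county_id"].nunique()
    )
    metrics["n_counties_invaded"] = float(n_counties)
    return safeguarded, amounts, summary, metrics


def run_all(cfg: RunConfig) -> dict[str, str]:
    """Run every stage and return a {relative path: sha256} manifest."""
    t0 = time.time()
    os.makedirs(cfg.out_dir, exist_ok=True)
    cfg.to_yaml(os.path.join(cfg.out_dir, "config_used.yaml"))
    log.info("run_all seed=%d out=%s", cfg.seed, cfg.out_dir)

    def _stage(name, fn, *args, **kw):
        t = time.time()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs (seed=%d)", name, time.time() - t, cfg.seed)
        return out

    landscape, occupancy, huc12, covariates, huc8_covs, ledger = _stage(
        "synth", generate_inputs, cfg
    )
    files: list[str] = []

    def _write(name: str, df: pd.DataFrame) -> None:
        path = os.path.join(cfg.out_dir, name)
        df.to_csv(path, index=False)
        files.append(name)

    synth.write_landscape_csvs(landscape, cfg.out_dir)
    files += ["counties.csv", "adjacency.csv", "watersheds.csv",
              "fine_units.csv", "overlap.csv"]
    _write("occupancy.csv", occupancy)
    _write("huc12_status.csv", huc12)
    _write("covariates_county.csv", covariates)
    _write("covariates_huc8.csv", huc8_covs)
    _write("resources.csv", ledger.resources)
    _write("prices.csv", ledger.prices)
    _write("yields.csv", ledger.yields)
    _write("cash_rents.csv", ledger.cash_rents)

    # prep
    window = list(range(cfg.pre_window[0], cfg.pre_window[1] + 1))
    deltas = _stage("prep", rates.annual_deltas, occupancy, landscape.areas)
    strata = rates.stratify(occupancy, window, tau=cfg.tau)
    _write("spread_rates.csv", deltas)
    _write("strata.csv", pd.DataFrame(
        [(c, name) for name, ids in strata.items() for c in sorted(ids)],
        columns=["county_id", "stratum"],
    ))
    _write("huc8_response.csv",
           rates.watershed_response(huc12, landscape.fine_to_coarse()))
    inv_s, ext_s = rates.observed_rates(
        huc12, range(cfg.rate_window[0], cfg.rate_window[1] + 1)
    )
    _write("observed_rates.csv", pd.DataFrame(
        {"year": inv_s.index, "invasion_rate": inv_s.to_numpy(),
         "extinction_rate": ext_s.reindex(inv_s.index).to_numpy()}
    ))

    observed = _observed_forecast_window(occupancy, cfg)
    forecasts: dict[str, pd.DataFrame] = {}
    for m in cfg.brt_models:
        result, models = _stage(
            f"brt:{m}", run_brt_model, m, landscape, occupancy, covariates,
            strata, cfg,
        )
        _write(f"forecast_{m}.csv", result.values)
        _write(f"transitions_{m}.csv", brt.forecast_transition_rates(result))
        imp = pd.concat(
            {k: v.importances for k, v in models.items()}, names=["stratum"]
        ).rename("importance").rename_axis(["stratum", "feature"]).reset_index()
        _write(f"importance_{m}.csv", imp)
        forecasts[m] = result.occupancy()

    occ_forecasts = _stage("occsim", run_occ_models, landscape, huc12,
                           huc8_covs, cfg)
    for name, df in occ_forecasts.items():
        _write(f"county_prop_{name}.csv", df)
        forecasts[name] = df

    metrics_by_model: dict[str, pd.Series] = {}
    for name, fc in forecasts.items():
        safeguarded, amounts, summary, metrics = _stage(
            f"value:{name}", value_model, fc, observed, ledger, landscape, name
        )
        _write(f"safeguard_amounts_{name}.csv", amounts)
        _write(f"safeguard_values_{name}.csv", summary.by_category)
        metrics_by_model[name] = metrics

    ens = valuation.ensemble_stats(metrics_by_model)
    _write("ensemble_summary.csv", ens.rename_axis("metric").reset_index())

    for name, df in report(forecasts, metrics_by_model, cfg).items():
        _write(f"report_{name}.csv", df)

    manifest = {f: _sha256(os.path.join(cfg.out_dir, f)) for f in sorted(files)}
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    log.info("run_all finished in %.1fs", time.time() - t0)
    return manifest


def newly_occupied_per_year(
    forecast: pd.DataFrame, tau: float, start_state: pd.Series | None = None
) -> pd.Series:
    """Counties crossing tau upward per forecast year, from yearly maps."""
    p = forecast.pivot(index="county_id", columns="year", values="prop")
    years = sorted(p.columns)
    out = {}
    prev = (
        start_state.reindex(p.index).fillna(0.0)
        if start_state is not None
        else pd.Series(0.0, index=p.index)
    )
    for y in years:
        out[y] = int(((prev <= tau) & (p[y] > tau)).sum())
        prev = p[y]
    return pd.Series(out, name="newly_occupied")


def report(
    forecasts: dict[str, pd.DataFrame],
    metrics_by_model: dict[str, pd.Series],
    cfg: RunConfig,
) -> dict[str, pd.DataFrame]:
    """Long-format summary tables with ensemble-mean rows.

    newly_occupied: per model-year counts of counties newly crossing tau.
    amounts / values: per model-category safeguarded amounts and dollars.
    """
    rows = []
    for name, fc in forecasts.items():
        series = newly_occupied_per_year(fc, cfg.tau)
        for year, v in series.items():
            rows.append((name, "newly_occupied", int(year), float(v)))
    occ = pd.DataFrame(rows, columns=["model", "metric", "year", "value"])
    mean_rows = (
        occ.groupby("year", as_index=False)["value"].mean()
        .assign(model="ensemble_mean", metric="newly_occupied")
    )
    occ = pd.concat([occ, mean_rows[occ.columns]], ignore_index=True)

    mdf = pd.DataFrame(metrics_by_model).rename_axis("metric")
    long = (
        mdf.reset_index()
        .melt("metric", var_name="model", value_name="value")
        .dropna(subset=["value"])
    )
    ens = (
        long.groupby("metric", as_index=False)["value"].mean()
        .assign(model="ensemble_mean")
    )
    long = pd.concat([long, ens[long.columns]], ignore_index=True)
    amounts = long[long["metric"].str.startswith("amount_")].reset_index(drop=True)
    values = long[long["metric"].str.startswith("dollars_")].reset_index(drop=True)
    return {"newly_occupied": occ, "amounts": amounts, "values": values}
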