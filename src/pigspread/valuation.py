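"""Safeguarded-resource accounting and valuation.

Converts forecast county occupancy into quantities of resources exposed
to the counterfactual spread (acres of crops/pasture/wetlands, head of
livestock) and dollar values for the valued subset, aggregated over the
forecast horizon and summarized across the model ensemble.

All dollar figures are undiscounted constant-2017 dollars; the resource
ledger is held constant across forecast years. Livestock and wetlands
are reported in physical units only (no annualized per-unit values
exist for them).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

#: exact survey-acre definition
KM2_PER_ACRE = 0.0040468564

#: categories that carry physical amounts but no dollar value
UNVALUED_CATEGORIES = frozenset({"livestock", "wetlands"})


def acres_to_km2(acres):
    """Convert acres to km² (1 acre = 0.0040468564 km²)."""
    a = np.asarray(acres, dtype=float)
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("acreage must be finite and nonnegative")
    out = a * KM2_PER_ACRE
    return float(out) if np.isscalar(acres) or a.ndim == 0 else out


def km2_to_acres(km2):
    """Convert km² to acres (reciprocal of :func:`acres_to_km2`)."""
    a = np.asarray(km2, dtype=float)
    if np.any(a < 0) or not np.all(np.isfinite(a)):
        raise ValueError("area must be finite and nonnegative")
    out = a / KM2_PER_ACRE
    return float(out) if np.isscalar(km2) or a.ndim == 0 else out


@dataclass(frozen=True)
class ResourceLedger:
    """County resource amounts plus the price/yield/rent tables.

    resources: county_id, category, resource, amount, unit
    prices: resource, price ($ per yield unit, national)
    yields: state_id, resource, yield_per_acre
    cash_rents: state_id, rent_per_acre (some states absent)
    national_rent: $/acre fallback where a state rent is missing
    """

    resources: pd.DataFrame
    prices: pd.DataFrame
    yields: pd.DataFrame
    cash_rents: pd.DataFrame
    national_rent: float


@dataclass(frozen=True)
class SafeguardSummary:
    """Per-category safeguarded totals for one forecast model.

    by_category: category, amount, unit, dollars (NaN where unvalued)
    """

    model: str
    by_category: pd.DataFrame
    total_dollars: float


def incremental_occupancy(
    forecast: pd.DataFrame, observed: pd.DataFrame
) -> pd.DataFrame:
    """Safeguarded proportion per county-year: max(0, forecast − observed).

    Both inputs carry (county_id, year, prop); the county universes must
    match. Counties observed occupied at the forecast extent (or more)
    contribute zero.
    """
    fc = forecast.rename(columns={"prop": "prop_fc"})
    ob = observed.rename(columns={"prop": "prop_obs"})
    f_counties = set(fc["county_id"].unique())
    o_counties = set(ob["county_id"].unique())
    if f_counties != o_counties:
        diff = f_counties.symmetric_difference(o_counties)
        raise ValueError(
            f"forecast/observed county universes differ (e.g. {sorted(diff)[:5]})"
        )
    m = fc.merge(ob, on=["county_id", "year"], how="left")
    m["prop_obs"] = m["prop_obs"].fillna(0.0)
    m["safeguarded_prop"] = np.clip(m["prop_fc"] - m["prop_obs"], 0.0, None)
    return m[["county_id", "year", "safeguarded_prop"]]


def threatened_amount(
    safeguarded: pd.DataFrame, resources: pd.DataFrame
) -> pd.DataFrame:
    """Resource amounts exposed per county-year-resource.

    amount = safeguarded proportion × county total for that resource;
    the ledger (2017-style snapshot) is held constant across years.
    Counties missing from the ledger contribute zero rows.
    """
    if (safeguarded["safeguarded_prop"] < 0).any():
        raise ValueError("negative safeguarded proportion")
    m = safeguarded.merge(resources, on="county_id", how="inner")
    m["amount_threatened"] = m["safeguarded_prop"] * m["amount"]
    return m[
        ["county_id", "year", "category", "resource", "amount_threatened", "unit"]
    ]


def per_acre_value(ledger: ResourceLedger) -> pd.DataFrame:
    """State-level $/acre for valued resources.

    Crops: national price × state yield. Pasture: state cash rent, with
    the national rent where a state has none. Wetlands and livestock are
    excluded (unvalued).
    """
    yl = ledger.yields.merge(ledger.prices, on="resource", how="left")
    missing = yl.loc[yl["price"].isna(), "resource"].unique()
    if len(missing):
        raise ValueError(
            f"no national price for crop(s): {sorted(missing)}"
        )
    yl["value_per_acre"] = yl["price"] * yl["yield_per_acre"]
    crops = yl[["state_id", "resource", "value_per_acre"]]

    states = ledger.yields["state_id"].unique()
    rent = (
        pd.DataFrame({"state_id": states})
        .merge(ledger.cash_rents, on="state_id", how="left")
    )
    rent["value_per_acre"] = rent["rent_per_acre"].fillna(ledger.national_rent)
    pasture = rent.assign(resource="pasture")[
        ["state_id", "resource", "value_per_acre"]
    ]
    return pd.concat([crops, pasture], ignore_index=True)


def value_safeguarded(
    amounts: pd.DataFrame,
    values: pd.DataFrame,
    county_states: pd.Series,
    model: str = "model",
) -> SafeguardSummary:
    """Aggregate safeguarded amounts and dollars across counties/years.

    ``county_states`` maps county_id -> state_id so state-level $/acre
    can be joined. Unvalued categories report amounts only.
    """
    if amounts.empty:
        empty = pd.DataFrame(
            columns=["category", "amount", "unit", "dollars"]
        )
        return SafeguardSummary(model, empty, 0.0)
    amt = amounts.copy()
    amt["state_id"] = amt["county_id"].map(county_states)
    amt = amt.merge(values, on=["state_id", "resource"], how="left")
    amt["dollars"] = amt["amount_threatened"] * amt["value_per_acre"]
    amt.loc[amt["category"].isin(UNVALUED_CATEGORIES), "dollars"] = np.nan

    by_cat = (
        amt.groupby(["category", "unit"], as_index=False)
        .agg(amount=("amount_threatened", "sum"), dollars=("dollars", "sum"))
    )
    by_cat.loc[by_cat["category"].isin(UNVALUED_CATEGORIES), "dollars"] = np.nan
    by_cat = by_cat[["category", "amount", "unit", "dollars"]]
    total = float(by_cat["dollars"].sum(skipna=True))
    return SafeguardSummary(model, by_cat, total)


def ensemble_stats(metrics: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Unweighted mean plus min/max of each metric across models.

    ``metrics`` maps model id -> Series of named metrics (county counts,
    category amounts, dollar totals). Returns a frame indexed by metric
    with columns mean/min/max.
    """
    if not metrics:
        raise ValueError("at least one model summary required")
    df = pd.DataFrame(metrics)
    return pd.DataFrame(
        {"mean": df.mean(axis=1), "min": df.min(axis=1), "max": df.max(axis=1)}
    )


def summary_metrics(summary: SafeguardSummary) -> pd.Series:
    """Flatten a SafeguardSummary into named metrics for ensembling."""
    s = {}
    for row in summary.by_category.itertuples(index=False):
        s[f"amount_{row.category}"] = row.amount
        if not np.isnan(row.dollars):
            s[f"dollars_{row.category}"] = row.dollars
    s["dollars_total"] = summary.total_dollars
    return pd.Series(s, dtype=float)
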