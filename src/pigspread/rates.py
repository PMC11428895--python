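"""Response-data preparation: occupancy deltas, strata, watershed rates.

Everything downstream consumes the outputs here: annual spread-rate
deltas on both the proportion and km² scales, per-county pre-program
mean rates, the persistent/transient/never stratification, the
coarse-watershed binomial response, and the observed annual
invasion/extinction rate series of fine watersheds.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default occupancy threshold: any strictly positive proportion counts
DEFAULT_TAU = 0.0


def _pivot_history(history: pd.DataFrame) -> pd.DataFrame:
    """County × year matrix of proportions; errors on missing cells."""
    p = history.pivot(index="county_id", columns="year", values="prop_occupied")
    if p.isna().any().any():
        bad = p.stack(future_stack=True)
        bad = bad[bad.isna()].index[0]
        raise ValueError(f"missing occupancy for county {bad[0]} year {bad[1]}")
    return p.sort_index().sort_index(axis=1)


def annual_deltas(history: pd.DataFrame, areas: pd.Series) -> pd.DataFrame:
    """Annual occupancy deltas per county.

    ``history`` holds (county_id, year, prop_occupied) for consecutive
    years; ``areas`` maps county_id -> km². Returns one row per county
    per year-pair with the delta indexed at the later year t:
    dprop = p_t − p_{t−1} (in [−1, 1]) and dkm2 = dprop × area.
    """
    p = _pivot_history(history)
    if p.shape[1] < 2:
        raise ValueError("need at least 2 years of occupancy")
    years = list(p.columns)
    if any(b - a != 1 for a, b in zip(years, years[1:])):
        raise ValueError(f"years not consecutive: {years}")
    d = p.diff(axis=1).iloc[:, 1:]
    out = (
        d.rename_axis(columns="year")
        .stack()
        .rename("dprop")
        .reset_index()
    )
    out["dkm2"] = out["dprop"] * out["county_id"].map(areas).to_numpy()
    return out.sort_values(["year", "county_id"], ignore_index=True)


def preprogram_mean(deltas: pd.DataFrame, window: Sequence[int]) -> pd.DataFrame:
    """Per-county arithmetic mean delta over the window, both scales.

    The window lists the delta years (each delta is indexed at the later
    year of its pair); the conventional pre-program window is 2009–2013.
    """
    window = list(window)
    if not window:
        raise ValueError("empty averaging window")
    avail = set(deltas["year"].unique())
    missing = sorted(set(window) - avail)
    if missing:
        raise ValueError(f"window years missing from delta table: {missing}")
    sub = deltas[deltas["year"].isin(window)]
    return (
        sub.groupby("county_id", as_index=False)
        .agg(mean_dprop=("dprop", "mean"), mean_dkm2=("dkm2", "mean"))
    )


def stratify(
    history: pd.DataFrame, window: Sequence[int], tau: float = DEFAULT_TAU
) -> dict[str, set[int]]:
    """Partition counties into persistent / transient / never sets.

    persistent: p > tau in every window year; transient: p > tau in at
    least one but not all; never: p <= tau throughout.
    """
    window = list(window)
    p = _pivot_history(history)
    missing = sorted(set(window) - set(p.columns))
    if missing:
        raise ValueError(f"window years missing from history: {missing}")
    occ = p[window] > tau
    n_occ = occ.sum(axis=1)
    persistent = set(p.index[n_occ == len(window)])
    never = set(p.index[n_occ == 0])
    transient = set(p.index) - persistent - never
    return {"persistent": persistent, "transient": transient, "never": never}


def watershed_response(
    huc12_status: pd.DataFrame, fine_to_coarse: pd.Series
) -> pd.DataFrame:
    """Binomial response per coarse watershed-year: (k invaded, n total)."""
    st = huc12_status.copy()
    mapped = st["huc12_id"].map(fine_to_coarse)
    if mapped.isna().any():
        orphan = st.loc[mapped.isna(), "huc12_id"].iloc[0]
        raise ValueError(f"fine watershed {orphan} has no coarse parent")
    st["huc8_id"] = mapped
    out = (
        st.groupby(["huc8_id", "year"], as_index=False)
        .agg(k=("invaded", "sum"), n=("invaded", "size"))
    )
    out["rate"] = out["k"] / out["n"]
    return out


def invasion_response(
    huc12_status: pd.DataFrame, fine_to_coarse: pd.Series
) -> pd.DataFrame:
    """Conditional invasion response per coarse watershed-year.

    k = fine units newly invaded between t−1 and t, n = fine units
    uninvaded at t−1. This is the binomial response for estimating the
    annual invasion probability of an uninvaded watershed (the
    occupancy-rate response from :func:`watershed_response` also counts
    carried-over presences).
    """
    st = huc12_status.copy()
    mapped = st["huc12_id"].map(fine_to_coarse)
    if mapped.isna().any():
        orphan = st.loc[mapped.isna(), "huc12_id"].iloc[0]
        raise ValueError(f"fine watershed {orphan} has no coarse parent")
    st["huc8_id"] = mapped
    wide = st.pivot(index="huc12_id", columns="year", values="invaded")
    years = sorted(wide.columns)
    f2c = st.drop_duplicates("huc12_id").set_index("huc12_id")["huc8_id"]
    rows = []
    for prev, year in zip(years, years[1:]):
        was = wide[prev].astype(bool)
        now = wide[year].astype(bool)
        sub = pd.DataFrame(
            {"huc8_id": f2c.loc[wide.index], "newly": (~was & now),
             "uninv": ~was}
        )
        g = sub.groupby("huc8_id").agg(k=("newly", "sum"), n=("uninv", "sum"))
        for h, row in g.iterrows():
            rows.append((int(h), int(year), int(row["k"]), int(row["n"])))
    return pd.DataFrame(rows, columns=["huc8_id", "year", "k", "n"])


def observed_rates(
    huc12_status: pd.DataFrame,
    window: Sequence[int],
    denominator: str = "uninvaded",
) -> tuple[pd.Series, pd.Series]:
    """System-wide annual invasion and extinction rate series.

    For each year-pair in the window: invasion rate = newly invaded fine
    units ÷ previously uninvaded units (or ÷ total units when
    ``denominator="total"``); extinction rate = newly extinct ÷
    previously invaded (÷ total likewise). Years whose denominator is
    zero are dropped with a logged warning. Series are indexed by the
    later year of each pair.
    """
    if denominator not in ("uninvaded", "total"):
        raise ValueError(f"unknown denominator rule {denominator!r}")
    window = list(window)
    if len(window) < 2:
        raise ValueError("need at least 2 years to compute rates")
    s = huc12_status.pivot(index="huc12_id", columns="year", values="invaded")
    missing = sorted(set(window) - set(s.columns))
    if missing:
        raise ValueError(f"window years missing from statuses: {missing}")
    s = s[window].astype(bool)
    n_total = len(s)
    inv, ext = {}, {}
    for prev, year in zip(window, window[1:]):
        was, now = s[prev], s[year]
        newly_inv = int((~was & now).sum())
        newly_ext = int((was & ~now).sum())
        d_inv = n_total if denominator == "total" else int((~was).sum())
        d_ext = n_total if denominator == "total" else int(was.sum())
        if d_inv > 0:
            inv[year] = newly_inv / d_inv
        else:
            log.warning("invasion rate undefined in %s (no uninvaded units)", year)
        if d_ext > 0:
            ext[year] = newly_ext / d_ext
        else:
            log.warning("extinction rate undefined in %s (no invaded units)", year)
    return (
        pd.Series(inv, name="invasion_rate", dtype=float),
        pd.Series(ext, name="extinction_rate", dtype=float),
    )


@dataclass(frozen=True)
class RateSummary:
    """Annual county transition rates over a window of year-pairs."""

    window: tuple[int, int]              # (first delta year, last delta year)
    n_years: int                         # number of year-pairs
    newly_occupied: int
    newly_unoccupied: int
    occupied_per_year: float
    unoccupied_per_year: float
    establishment_km2_mean: float
    establishment_km2_ci: tuple[float, float]
    establishment_prop_mean: float
    establishment_prop_ci: tuple[float, float]


def _mean_ci(x: np.ndarray) -> tuple[float, tuple[float, float]]:
    if len(x) == 0:
        return float("nan"), (float("nan"), float("nan"))
    m = float(np.mean(x))
    if len(x) == 1:
        return m, (m, m)
    se = float(np.std(x, ddof=1)) / math.sqrt(len(x))
    return m, (m - 1.96 * se, m + 1.96 * se)


def rate_summary(
    history: pd.DataFrame,
    window: Sequence[int],
    areas: pd.Series,
    tau: float = DEFAULT_TAU,
) -> RateSummary:
    """Count threshold-crossing transitions over a window of year-pairs.

    ``window`` lists the transition years (each transition is between
    year t−1 and t). Newly occupied = counties crossing tau upward;
    newly unoccupied = crossing downward; rates divide the totals by the
    number of year-pairs. Establishment size (km² and proportion in the
    first year of occupancy) is summarized with a normal-approximation
    95% CI.
    """
    window = list(window)
    if not window:
        raise ValueError("window must contain at least one transition year")
    p = _pivot_history(history)
    needed = sorted(set(window) | {min(window) - 1})
    missing = sorted(set(needed) - set(p.columns))
    if missing:
        raise ValueError(f"history missing years {missing}")

    n_up = n_down = 0
    est_km2, est_prop = [], []
    for year in window:
        prev, now = p[year - 1], p[year]
        up = (prev <= tau) & (now > tau)
        down = (prev > tau) & (now <= tau)
        n_up += int(up.sum())
        n_down += int(down.sum())
        props = now[up]
        est_prop.extend(props.to_numpy())
        est_km2.extend((props * props.index.map(areas)).to_numpy())

    km2_mean, km2_ci = _mean_ci(np.asarray(est_km2))
    prop_mean, prop_ci = _mean_ci(np.asarray(est_prop))
    n_years = len(window)
    return RateSummary(
        window=(min(window), max(window)),
        n_years=n_years,
        newly_occupied=n_up,
        newly_unoccupied=n_down,
        occupied_per_year=n_up / n_years,
        unoccupied_per_year=n_down / n_years,
        establishment_km2_mean=km2_mean,
        establishment_km2_ci=km2_ci,
        establishment_prop_mean=prop_mean,
        establishment_prop_ci=prop_ci,
    )
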