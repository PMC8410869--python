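"""Target-group pseudo-absences with environmental stratification.

Background (pseudo-absence) sites are drawn from the pooled sampling sites
of the target group — so absences inherit the survey-effort distribution —
after stratifying the environment on SST x MLD.  The number of background
sites drawn from a stratum is proportional to the number of target-group
(cell, month) sites it holds (largest-remainder rounding), the focal
species' own presences are never drawn, and, by default, ten times more
background than presence rows are produced.  Presence rows carry weight 1
and background rows ``n_presence / n_background`` so the two classes have
equal total weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .occurrences import GriddedPresences
from .predictors import match_predictors

__all__ = ["StratumTable", "stratify_environment", "draw_background"]


@dataclass
class StratumTable:
    """Equal-frequency SST x MLD strata over the target-group sites."""

    sst_edges: np.ndarray
    mld_edges: np.ndarray
    table: pd.DataFrame  # stratum, count, weight
    site_strata: pd.DataFrame  # target sites with their stratum id

    def assign(self, sst: np.ndarray, mld: np.ndarray) -> np.ndarray:
        i = np.clip(np.searchsorted(self.sst_edges, sst, side="right") - 1, 0,
                    len(self.sst_edges) - 2)
        j = np.clip(np.searchsorted(self.mld_edges, mld, side="right") - 1, 0,
                    len(self.mld_edges) - 2)
        return i * (len(self.mld_edges) - 1) + j


def _quantile_edges(x: np.ndarray, n_bins: int, label: str) -> np.ndarray:
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.unique(np.quantile(x, qs))
    if len(edges) - 1 < n_bins:
        warnings.warn(
            f"{label}: only {len(edges) - 1} distinct bins available "
            f"(requested {n_bins})"
        )
    if len(edges) < 2:  # constant field -> single stratum
        edges = np.array([edges[0] - 0.5, edges[0] + 0.5])
    edges[0] -= 1e-9
    edges[-1] += 1e-9
    return edges


def stratify_environment(
    target_group: GriddedPresences,
    stack: xr.Dataset,
    n_sst_bins: int = 10,
    n_mld_bins: int = 10,
) -> StratumTable:
    """Equal-frequency SST/MLD stratification of the target-group sites.

    Stratum weights are proportional to target-group site counts and sum to
    one over the non-empty strata.
    """
    sites = target_group.all_sites()
    if sites.empty:
        raise ValueError("target group has no sites")
    env = match_predictors(stack, sites, ["SST", "MLD"])
    sst = env["SST"].to_numpy(float)
    mld = env["MLD"].to_numpy(float)
    sst_edges = _quantile_edges(sst, n_sst_bins, "SST")
    mld_edges = _quantile_edges(mld, n_mld_bins, "MLD")

    tmp = StratumTable(sst_edges, mld_edges, pd.DataFrame(), pd.DataFrame())
    strata = tmp.assign(sst, mld)
    counts = pd.Series(strata).value_counts().sort_index()
    table = pd.DataFrame(
        {"stratum": counts.index, "count": counts.values}
    )
    table["weight"] = table["count"] / table["count"].sum()
    site_strata = sites.copy()
    site_strata["stratum"] = strata
    return StratumTable(sst_edges, mld_edges, table, site_strata)


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` across strata proportional to weights."""
    quota = weights / weights.sum() * total
    alloc = np.floor(quota).astype(int)
    remainder = quota - alloc
    short = total - alloc.sum()
    if short > 0:
        order = np.argsort(-remainder, kind="stable")
        alloc[order[:short]] += 1
    return alloc


def draw_background(
    species_id: str,
    presences: GriddedPresences,
    target_group: GriddedPresences,
    strata: StratumTable,
    stack: xr.Dataset,
    ratio: int = 10,
    seed: int = 0,
    predictor_names=None,
) -> pd.DataFrame:
    """Build the training set (presences + stratified background) for a species.

    Exactly ``ratio * n_presence`` background sites are sampled without
    replacement from the target-group sites the species does not occupy,
    allocated across strata proportionally to the stratum weights.  If a
    stratum runs out of free sites the shortfall is drawn with replacement
    and a warning is emitted — never silently.
    """
    own = presences.table[presences.table["species_id"] == species_id]
    n_pres = len(own)
    if n_pres == 0:
        raise ValueError(f"species {species_id!r} has no presences")
    rng = np.random.default_rng(seed)

    sites = strata.site_strata.copy()
    own_keys = set(zip(own["ilat"], own["ilon"], own["month"]))
    key = list(zip(sites["ilat"], sites["ilon"], sites["month"]))
    free = sites.loc[[k not in own_keys for k in key]]
    if free.empty:
        raise ValueError(
            f"species {species_id!r} occupies every target-group site; "
            "no background candidates remain"
        )

    n_bg = ratio * n_pres
    st_ids = strata.table["stratum"].to_numpy()
    weights = strata.table["weight"].to_numpy(float)
    alloc = _largest_remainder(weights, n_bg)

    chunks = []
    short_strata = []
    empty_strata = []
    for sid, n_take in zip(st_ids, alloc):
        if n_take == 0:
            continue
        pool = free[free["stratum"] == sid]
        if len(pool) == 0:
            pool = free  # stratum fully occupied by the species: fall back
            empty_strata.append(int(sid))
        if n_take <= len(pool):
            idx = rng.choice(len(pool), size=n_take, replace=False)
        else:
            short_strata.append(int(sid))
            idx = rng.choice(len(pool), size=n_take, replace=True)
        chunks.append(pool.iloc[idx])
    if empty_strata:
        warnings.warn(
            f"{species_id!r}: {len(empty_strata)} strata had no free sites; "
            "sampled from the pooled free sites instead"
        )
    if short_strata:
        warnings.warn(
            f"{species_id!r}: {len(short_strata)} strata short of free sites; "
            "sampled with replacement there"
        )
    bg = pd.concat(chunks, ignore_index=True)

    pres_rows = own[["ilat", "ilon", "month", "lat", "lon"]].copy()
    pres_rows["response"] = 1.0
    pres_rows["weight"] = 1.0
    bg_rows = bg[["ilat", "ilon", "month", "lat", "lon"]].copy()
    bg_rows["response"] = 0.0
    bg_rows["weight"] = n_pres / len(bg_rows)
    out = pd.concat([pres_rows, bg_rows], ignore_index=True)
    out.insert(0, "species_id", species_id)

    names = predictor_names
    if names is None:
        names = [v for v in stack.data_vars if v not in ("uo", "vo", "bathymetry")]
    vals = match_predictors(stack, out, names)
    return pd.concat([out, vals], axis=1)
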