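"""Record-level quality control, deduplication and grid binning.

Raw occurrence tables (one row per species record) pass through a frozen
chain of filters before being binned onto the monthly analysis grid:

1. missing spatial coordinate
2. incomplete sampling date (day/month/year)
3. collection year before 1800
4. no sampling depth at all
5. name not resolved to species level
6. fossil / sediment-core source (keyword match)
7. surface salinity < 20 (brackish / inland)
8. seafloor shallower than 200 m (coastal)
9. maximal net tow depth > 500 m (below the euphotic habitat;
   the record depth is used when a maximal depth is absent)

The order is part of the contract: per-step removal counts depend on it and
are reported, not hidden.  Duplicates (same species, date, depth and 0.25
degree cell) are then collapsed to a single record, and the survivors are
binned to per-(cell, month) presences.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

__all__ = [
    "QCRules",
    "FilterReport",
    "GriddedPresences",
    "filter_occurrences",
    "deduplicate",
    "bin_to_grid",
]

REQUIRED_COLUMNS = [
    "species_id",
    "decimal_longitude",
    "decimal_latitude",
    "year",
    "month",
    "day",
    "depth_m",
    "max_net_depth_m",
    "salinity_at_point",
    "bathymetry_m",
    "source",
]

DEFAULT_FOSSIL_KEYWORDS = (
    "fossil",
    "sediment",
    "drill",
    "core",
    "holocene",
    "pleistocene",
)

_NON_SPECIES_EPITHETS = {"sp", "sp.", "spp", "spp.", "indet", "indet.", "cf", "cf."}


@dataclass(frozen=True)
class QCRules:
    """Thresholds of the quality-control chain.

    ``max_net_depth_m=None`` disables the net-depth rule — the profile used
    for phytoplankton tables, which arrive pre-screened for sampling depth.
    """

    min_year: int = 1800
    min_salinity: float = 20.0
    min_bathymetry_m: float = 200.0
    max_net_depth_m: float | None = 500.0
    dedup_cell_deg: float = 0.25
    fossil_keywords: tuple = DEFAULT_FOSSIL_KEYWORDS

    @classmethod
    def zooplankton(cls) -> "QCRules":
        return cls()

    @classmethod
    def phytoplankton(cls) -> "QCRules":
        return cls(max_net_depth_m=None)


@dataclass
class FilterReport:
    """Per-rule removal counts; removals plus retained sum to the input."""

    input_rows: int
    removed: dict = field(default_factory=dict)
    retained: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {"input_rows": self.input_rows, "removed": self.removed, "retained": self.retained},
            indent=2,
        )

    def check(self) -> bool:
        return sum(self.removed.values()) + self.retained == self.input_rows


def _is_species_level(name) -> bool:
    if not isinstance(name, str):
        return False
    tokens = name.strip().split()
    if len(tokens) < 2:
        return False
    return tokens[1].lower() not in _NON_SPECIES_EPITHETS


def filter_occurrences(
    raw: pd.DataFrame,
    rules: QCRules | None = None,
    synonym_table: dict | None = None,
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the QC chain in its frozen order.

    ``synonym_table`` (accepted name -> canonical name) is applied before the
    species-level check.  Returns the retained rows and a
    :class:`FilterReport` with per-step counts.
    """
    rules = rules or QCRules()
    missing = [c for c in REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise KeyError(f"occurrence table missing columns: {missing}")

    df = raw.copy()
    if synonym_table:
        df["species_id"] = df["species_id"].map(lambda s: synonym_table.get(s, s))

    report = FilterReport(input_rows=len(df))

    def drop(name: str, mask_bad: pd.Series):
        nonlocal df
        n = int(mask_bad.sum())
        report.removed[name] = n
        df = df.loc[~mask_bad]

    drop(
        "missing_coordinates",
        df["decimal_longitude"].isna() | df["decimal_latitude"].isna(),
    )
    drop(
        "incomplete_date",
        df["year"].isna() | df["month"].isna() | df["day"].isna(),
    )
    drop("year_before_min", df["year"] < rules.min_year)
    drop("no_depth", df["depth_m"].isna() & df["max_net_depth_m"].isna())
    drop("not_species_level", ~df["species_id"].map(_is_species_level))
    kw = tuple(k.lower() for k in rules.fossil_keywords)
    src = df["source"].fillna("").str.lower()
    drop("fossil_or_sediment", src.map(lambda s: any(k in s for k in kw)))
    drop("low_salinity", df["salinity_at_point"] < rules.min_salinity)
    drop("shallow_bathymetry", df["bathymetry_m"] < rules.min_bathymetry_m)
    if rules.max_net_depth_m is not None:
        eff_depth = df["max_net_depth_m"].fillna(df["depth_m"])
        drop("net_depth_too_deep", eff_depth > rules.max_net_depth_m)
    report.retained = len(df)
    assert report.check()
    return df.reset_index(drop=True), report


def deduplicate(occ: pd.DataFrame, cell_deg: float = 0.25) -> pd.DataFrame:
    """Collapse duplicates: same species, date, depth and ``cell_deg`` cell.

    The first-seen record of each duplicate group is kept.  Idempotent and
    never increases the row count.
    """
    if cell_deg <= 0:
        raise ValueError("cell_deg must be positive")
    lon = GridSpec.wrap_lon(occ["decimal_longitude"].to_numpy(float))
    lat = occ["decimal_latitude"].to_numpy(float)
    key = occ.assign(
        _ci=np.floor(lon / cell_deg).astype(int),
        _cj=np.floor(lat / cell_deg).astype(int),
    )
    out = key.drop_duplicates(
        subset=["species_id", "year", "month", "day", "depth_m", "_ci", "_cj"],
        keep="first",
    )
    return out.drop(columns=["_ci", "_cj"]).reset_index(drop=True)


@dataclass
class GriddedPresences:
    """Per-species presences on the monthly analysis grid.

    ``table`` has one row per distinct (species, cell, month) presence with
    integer indices ``ilat``/``ilon`` and the cell-center coordinates.
    """

    spec: GridSpec
    table: pd.DataFrame

    @property
    def species(self) -> list:
        return sorted(self.table["species_id"].unique())

    def counts(self) -> pd.Series:
        """Presence count (distinct cell-month pairs) per species."""
        return self.table.groupby("species_id").size()

    def sites_of(self, species_id: str) -> set:
        sub = self.table[self.table["species_id"] == species_id]
        return set(zip(sub["ilat"], sub["ilon"], sub["month"]))

    def all_sites(self) -> pd.DataFrame:
        """Distinct (cell, month) sites of the pooled table (target group)."""
        return (
            self.table[["ilat", "ilon", "month", "lat", "lon"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )

    def subset(self, species_ids) -> "GriddedPresences":
        keep = self.table["species_id"].isin(set(species_ids))
        return GriddedPresences(self.spec, self.table[keep].reset_index(drop=True))


def bin_to_grid(occ: pd.DataFrame, spec: GridSpec) -> GriddedPresences:
    """Bin records to monthly grid-cell presences.

    A species is present in a (cell, month) if it was recorded there at
    least once; the count of distinct pairs is the species' presence count
    used everywhere downstream.  Records outside the grid's latitude bounds
    are dropped with a warning.
    """
    lon = occ["decimal_longitude"].to_numpy(float)
    lat = occ["decimal_latitude"].to_numpy(float)
    ilat, ilon = spec.cell_of(lon, lat)
    ok = ilat >= 0
    n_bad = int((~ok).sum())
    if n_bad:
        warnings.warn(f"dropping {n_bad} records outside the grid bounds")
    month = occ["month"].to_numpy(float).astype(int)
    tab = pd.DataFrame(
        {
            "species_id": occ["species_id"].to_numpy()[ok],
            "ilat": ilat[ok],
            "ilon": ilon[ok],
            "month": month[ok],
        }
    ).drop_duplicates()
    tab["lat"] = spec.lat_centers[tab["ilat"]]
    tab["lon"] = spec.lon_centers[tab["ilon"]]
    return GriddedPresences(spec, tab.reset_index(drop=True))
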