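"""Synthetic ocean worlds with known ground truth.

This module emulates, at configurable resolution, the ingredients of a
global plankton niche-modelling study: monthly 1-degree-style environmental
climatologies (temperature with a latitudinal gradient and seasonality,
nutrients anti-correlated with temperature, chlorophyll, mixed-layer depth,
irradiance, oxygen, winds and eddy velocity components), virtual species
with unimodal (product-of-Gaussians) environmental niches, spatially and
seasonally biased occurrence sampling with a configurable contamination of
records that violate quality control, and per-pseudo-ESM future anomaly
fields of configurable amplitude.

Everything is deterministic given a seed, so downstream recovery tests can
compare estimates against the generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage

from .grids import GridSpec

__all__ = [
    "EnvConfig",
    "SpeciesConfig",
    "ESMConfig",
    "VirtualSpecies",
    "AnomalySet",
    "generate_environment",
    "generate_species",
    "sample_occurrences",
    "generate_future_anomalies",
    "uniform_effort",
    "biased_effort",
]

OCC_COLUMNS = [
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

_GENERA = [
    "Thalassimo", "Calanopsis", "Pseudonitza", "Oithonella", "Ceratiums",
    "Acartiodes", "Fragilariopsis", "Temorella", "Chaetocerus", "Euphausina",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class EnvConfig:
    """Amplitudes shaping the synthetic climatologies.

    ``sst_seasonal_amplitude`` is the peak-to-centre seasonal swing at the
    poles (degC); setting it to 0 makes SST month-invariant, so the derived
    annual SST range is identically zero.
    """

    sst_equator: float = 28.0
    sst_pole: float = -1.0
    sst_seasonal_amplitude: float = 4.0
    sst_noise_sd: float = 0.6
    no3_max: float = 28.0
    nutrient_noise_sd: float = 0.15
    chl_background: float = 0.05
    mld_max: float = 150.0
    par_max: float = 58.0
    do2_intercept: float = 8.8
    do2_slope: float = -0.22
    wind_base: float = 4.0
    eddy_velocity_sd: float = 0.18
    smooth_sigma: float = 1.0


@dataclass(frozen=True)
class SpeciesConfig:
    """Distributions used to draw virtual species.

    Niche centers are drawn inside the realized environmental ranges (the
    5th-95th percentile band of each niche predictor).  ``size_temp_rho``
    couples log body/cell size to the thermal niche center via a Gaussian
    copula (negative = warm species are small, the field's expectation).
    """

    niche_predictors: tuple = ("SST",)
    breadth_ranges: dict = field(default_factory=lambda: {"SST": (2.5, 5.5)})
    secondary_breadth_factor: float = 2.0
    max_suitability_range: tuple = (0.7, 1.0)
    phyto_fraction: float = 0.4
    size_temp_rho: float = -0.6
    log10_size_mean: float = 3.0
    log10_size_sd: float = 0.8
    center_quantiles: tuple = (0.05, 0.95)


@dataclass(frozen=True)
class ESMConfig:
    """A pseudo earth-system model's end-of-century forcing.

    ``sst_amplitude`` is the surface warming (degC) applied with the chosen
    spatial ``pattern``; the other fields respond proportionally to the local
    warming (warming stratifies the water column: nutrients, chlorophyll,
    oxygen and mixed-layer depth all decline).
    """

    esm_id: str
    sst_amplitude: float = 3.0
    pattern: str = "uniform"  # "uniform" | "polar"
    nutrient_sensitivity: float = -0.04  # fractional change per degC warming
    chl_sensitivity: float = -0.03
    do2_sensitivity: float = -0.15  # ml/l per degC
    mld_sensitivity: float = -0.02


@dataclass
class VirtualSpecies:
    """Ground-truth species: a product-of-Gaussians suitability surface."""

    id: str
    niche_centers: dict
    niche_breadths: dict
    max_suitability: float
    trait_size: float
    trophic_group: str  # "phyto" | "zoo"
    target_group_label: str = "total"

    def suitability(self, values: dict) -> np.ndarray:
        """Suitability in [0, max_suitability] for mapping name -> array."""
        out = None
        for name, center in self.niche_centers.items():
            x = np.asarray(values[name], dtype=float)
            b = self.niche_breadths[name]
            term = np.exp(-0.5 * ((x - center) / b) ** 2)
            out = term if out is None else out * term
        return self.max_suitability * out


@dataclass
class AnomalySet:
    """Monthly delta fields (future minus baseline) for one pseudo-ESM."""

    esm_id: str
    deltas: xr.Dataset

    def apply(self, env: xr.Dataset) -> xr.Dataset:
        out = env.copy()
        for name in self.deltas.data_vars:
            if name in out:
                out[name] = out[name] + self.deltas[name]
        return out


# ---------------------------------------------------------------------------
# environment
# ---------------------------------------------------------------------------
def _smooth_noise(rng, shape, sigma):
    """Seeded smooth random field with unit-ish variance."""
    raw = rng.standard_normal(shape)
    if sigma > 0:
        raw = ndimage.gaussian_filter(raw, sigma=sigma, mode="wrap")
        sd = raw.std()
        if sd > 0:
            raw = raw / sd
    return raw


def generate_environment(
    spec: GridSpec, seed: int, config: EnvConfig | None = None
) -> xr.Dataset:
    """Generate monthly climatologies of the primary environmental fields.

    Returns an :class:`xarray.Dataset` with dims ``(month, lat, lon)`` for
    SST, SSS, NO3, PO4, SiOH4, dO2, Chl, PAR, MLD, wind, and the eddy
    velocity components uo/vo, plus a static ``bathymetry`` field
    (dims ``lat, lon``).  SST decreases with |latitude| in every month and
    carries a hemisphere-antiphased sinusoidal seasonal cycle; nutrients are
    negatively correlated with SST.  Deterministic given ``seed``.
    """
    if not isinstance(spec, GridSpec):
        raise TypeError("spec must be a GridSpec")
    cfg = config or EnvConfig()
    rng = np.random.default_rng(seed)

    months = spec.month_values
    lat = spec.lat_centers
    lon = spec.lon_centers
    nlat, nlon = spec.n_lat, spec.n_lon
    lat2 = lat[:, None] * np.ones((1, nlon))
    lat_rad = np.deg2rad(lat2)
    hemi = np.where(lat2 >= 0, 1.0, -1.0)

    def monthly(fn):
        return np.stack([fn(m) for m in months])

    # --- SST: meridional gradient + seasonality + static spatial texture
    sst_base = cfg.sst_pole + (cfg.sst_equator - cfg.sst_pole) * np.cos(lat_rad) ** 1.5
    sst_texture = cfg.sst_noise_sd * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    seas_scale = 0.25 + 0.75 * np.abs(lat2) / 90.0

    def sst_month(m):
        # peaks in August north of the equator, February south of it
        cyc = np.cos(2.0 * np.pi * (m - 8) / 12.0)
        return sst_base + sst_texture + cfg.sst_seasonal_amplitude * seas_scale * hemi * cyc

    sst = monthly(sst_month)

    # --- nutrients: decline with SST (stratification proxy)
    nut_noise = cfg.nutrient_noise_sd * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    po4_noise = cfg.nutrient_noise_sd * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    si_noise = cfg.nutrient_noise_sd * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    no3 = np.clip(
        cfg.no3_max / (1.0 + np.exp((sst - 11.0) / 4.5)) * (1.0 + nut_noise) + 0.05,
        0.01,
        None,
    )
    po4 = np.clip(no3 / 16.0 * (1.0 + 0.3 * po4_noise) + 0.02, 0.005, None)
    sioh4 = np.clip(0.9 * no3 * (1.0 + 0.5 * si_noise) + 0.5, 0.01, None)

    # --- chlorophyll follows nutrients (lognormal texture)
    chl_noise = _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    chl = cfg.chl_background + 0.08 * no3**0.8 * np.exp(0.4 * chl_noise)

    # --- oxygen at depth: anti-correlated with SST
    do2_noise = 0.15 * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    do2 = np.clip(cfg.do2_intercept + cfg.do2_slope * sst + do2_noise, 0.3, None)

    # --- PAR: solar geometry with a seasonally migrating declination
    def par_month(m):
        decl = 23.4 * np.cos(2.0 * np.pi * (m - 6.5) / 12.0)
        elev = np.cos(np.deg2rad(lat2 - decl))
        return np.clip(cfg.par_max * elev, 1.0, None)

    par = monthly(par_month)

    # --- MLD: deep winter mixed layers at high latitude
    mld_noise = 0.2 * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)

    def mld_month(m):
        north = 0.5 * (1.0 + np.cos(2.0 * np.pi * (m - 2) / 12.0))
        south = 0.5 * (1.0 + np.cos(2.0 * np.pi * (m - 8) / 12.0))
        winter = np.where(lat2 >= 0, north, south)
        depth = 12.0 + cfg.mld_max * (np.abs(lat2) / 90.0) ** 1.2 * winter
        return np.clip(depth * (1.0 + mld_noise), 5.0, None)

    mld = monthly(mld_month)

    # --- wind: mid-latitude westerly maxima
    wind_noise = 0.6 * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma)
    wind_lat = cfg.wind_base + 6.0 * np.exp(-(((np.abs(lat2) - 45.0) / 16.0) ** 2))
    wind = monthly(lambda m: np.clip(wind_lat + wind_noise, 0.5, None))

    # --- eddy velocity components (anomalies around the mean flow)
    eddy_scale = cfg.eddy_velocity_sd * (0.4 + 0.6 * np.exp(-((lat2 / 35.0) ** 2)))
    uo = np.stack(
        [eddy_scale * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma) for _ in months]
    )
    vo = np.stack(
        [eddy_scale * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma) for _ in months]
    )

    # --- salinity & bathymetry (ambient values; QC outliers are injected
    #     per-record by the occurrence sampler, not present in the fields)
    sss = 35.0 - 3.0 * (np.abs(lat2) / 90.0) ** 2 + 0.8 * _smooth_noise(
        rng, (nlat, nlon), cfg.smooth_sigma
    )
    bathy = np.clip(
        3800.0 + 900.0 * _smooth_noise(rng, (nlat, nlon), cfg.smooth_sigma), 1000.0, None
    )

    coords = {"month": months, "lat": lat, "lon": lon}
    dims = ("month", "lat", "lon")

    def da(arr):
        return xr.DataArray(arr, coords=coords, dims=dims)

    ds = xr.Dataset(
        {
            "SST": da(sst),
            "SSS": da(np.broadcast_to(sss, (len(months), nlat, nlon)).copy()),
            "NO3": da(no3),
            "PO4": da(po4),
            "SiOH4": da(sioh4),
            "dO2": da(do2),
            "Chl": da(chl),
            "PAR": da(par),
            "MLD": da(mld),
            "wind": da(wind),
            "uo": da(uo),
            "vo": da(vo),
        }
    )
    ds["bathymetry"] = xr.DataArray(
        bathy, coords={"lat": lat, "lon": lon}, dims=("lat", "lon")
    )
    ds.attrs["grid"] = spec
    ds.attrs["seed"] = seed
    return ds


# ---------------------------------------------------------------------------
# species
# ---------------------------------------------------------------------------
def generate_species(
    n_species: int,
    env: xr.Dataset,
    seed: int,
    config: SpeciesConfig | None = None,
) -> list[VirtualSpecies]:
    """Draw ``n_species`` virtual species with niches inside the realized
    environmental ranges of ``env``.

    Species get binomial-style names (``Genus epithetNNN``) so that the
    species-level QC check behaves as it does on real tables.
    """
    if n_species < 1:
        raise ValueError("n_species must be >= 1")
    cfg = config or SpeciesConfig()
    if not cfg.niche_predictors:
        raise ValueError("niche_predictors must not be empty")
    rng = np.random.default_rng(seed)

    ranges = {}
    for name in cfg.niche_predictors:
        if name not in env:
            raise KeyError(f"niche predictor {name!r} not in environment")
        vals = np.asarray(env[name]).ravel()
        vals = vals[np.isfinite(vals)]
        lo, hi = np.quantile(vals, cfg.center_quantiles)
        ranges[name] = (lo, hi)

    thermal = cfg.niche_predictors[0]
    rho = float(np.clip(cfg.size_temp_rho, -0.999, 0.999))
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal(np.zeros(2), cov, size=n_species)
    from scipy.stats import norm

    u_thermal = norm.cdf(z[:, 0])
    z_size = z[:, 1]

    species: list[VirtualSpecies] = []
    n_phyto = int(round(cfg.phyto_fraction * n_species))
    for i in range(n_species):
        centers, breadths = {}, {}
        for name in cfg.niche_predictors:
            lo, hi = ranges[name]
            if name == thermal:
                centers[name] = lo + u_thermal[i] * (hi - lo)
            else:
                centers[name] = rng.uniform(lo, hi)
            b_lo, b_hi = cfg.breadth_ranges.get(
                name, ((hi - lo) / 8.0, (hi - lo) / 3.0)
            )
            breadths[name] = rng.uniform(b_lo, b_hi)
        size = 10.0 ** (cfg.log10_size_mean + cfg.log10_size_sd * z_size[i])
        genus = _GENERA[int(rng.integers(len(_GENERA)))]
        species.append(
            VirtualSpecies(
                id=f"{genus} virtualis{i:03d}",
                niche_centers=centers,
                niche_breadths=breadths,
                max_suitability=float(rng.uniform(*cfg.max_suitability_range)),
                trait_size=float(size),
                trophic_group="phyto" if i < n_phyto else "zoo",
            )
        )
    return species


def species_suitability_cube(
    species: list[VirtualSpecies], env: xr.Dataset
) -> xr.DataArray:
    """True suitability for each species on the environment grid.

    dims: (species, month, lat, lon).  Derived niche predictors (log fields
    etc.) are computed on the fly when a niche asks for one.
    """
    needed = {n for sp in species for n in sp.niche_centers}
    fields = {}
    ds = env
    missing = needed - set(env.data_vars)
    if missing:
        from .predictors import derive_predictors

        ds = derive_predictors(env)
    for n in needed:
        fields[n] = np.asarray(ds[n])
    cube = np.stack([sp.suitability(fields) for sp in species])
    return xr.DataArray(
        cube,
        coords={
            "species": [sp.id for sp in species],
            "month": env["month"].values,
            "lat": env["lat"].values,
            "lon": env["lon"].values,
        },
        dims=("species", "month", "lat", "lon"),
    )


# ---------------------------------------------------------------------------
# sampling effort & occurrences
# ---------------------------------------------------------------------------
def uniform_effort(spec: GridSpec) -> xr.DataArray:
    """Spatially and seasonally uniform sampling effort."""
    f = spec.empty_field(monthly=True, fill=1.0)
    return f


def biased_effort(
    spec: GridSpec,
    uniform_weight: float = 0.3,
    center_lon: float = -30.0,
    center_lat: float = 50.0,
    sigma_deg: float = 25.0,
    summer_bias: float = 0.5,
) -> xr.DataArray:
    """Effort concentrated around a basin (North Atlantic analog) with a
    seasonal tilt toward local summer — a mixture of a uniform floor and a
    Gaussian spatial bump."""
    lon = spec.lon_centers[None, :]
    lat = spec.lat_centers[:, None]
    dlon = (GridSpec.wrap_lon(lon - center_lon) + 180.0) % 360.0 - 180.0
    bump = np.exp(-0.5 * ((dlon / sigma_deg) ** 2 + ((lat - center_lat) / sigma_deg) ** 2))
    months = spec.month_values
    hemi = np.where(lat >= 0, 1.0, -1.0)
    fields = []
    for m in months:
        seas = 1.0 + summer_bias * hemi * np.cos(2.0 * np.pi * (m - 7.5) / 12.0)
        fields.append(uniform_weight + (1 - uniform_weight) * bump * np.clip(seas, 0.1, None))
    return xr.DataArray(
        np.stack(fields),
        coords={"month": months, "lat": spec.lat_centers, "lon": spec.lon_centers},
        dims=("month", "lat", "lon"),
    )


_CONTAMINATION_KINDS = (
    "missing_coord",
    "incomplete_date",
    "pre1800",
    "missing_depth",
    "genus_only",
    "fossil_source",
    "low_salinity",
    "shallow_bathymetry",
    "deep_net",
)


def sample_occurrences(
    species: list[VirtualSpecies],
    env: xr.Dataset,
    effort: xr.DataArray | None,
    n_records: int,
    seed: int,
    contamination: float = 0.0,
) -> pd.DataFrame:
    """Draw a raw occurrence table.

    Records are drawn from the joint categorical distribution
    ``p(species, month, cell) ∝ effort(month, cell) * suitability`` so that,
    under uniform effort, expected per-cell counts are proportional to the
    summed suitability.  A ``contamination`` fraction of rows is perturbed to
    violate exactly one quality-control rule each (cycling through the rule
    list), giving the QC filter chain known ground truth.
    """
    spec: GridSpec = env.attrs["grid"]
    if effort is None:
        effort = uniform_effort(spec)
    eff = np.asarray(effort, dtype=float)
    if (eff < 0).any():
        raise ValueError("effort must be non-negative")
    if not np.any(eff > 0):
        raise ValueError("effort must not be all zero")
    rng = np.random.default_rng(seed)

    cube = np.asarray(species_suitability_cube(species, env))  # (sp, mo, la, lo)
    probs = cube * eff[None, ...]
    probs = np.nan_to_num(probs, nan=0.0)
    total = probs.sum()
    if total <= 0:
        raise ValueError("effort x suitability has no mass")
    flat = probs.ravel() / total
    draws = rng.choice(flat.size, size=n_records, p=flat)
    isp, imo, ila, ilo = np.unravel_index(draws, probs.shape)

    lat_c = spec.lat_centers[ila]
    lon_c = spec.lon_centers[ilo]
    half = spec.cell_size / 2.0
    lats = lat_c + rng.uniform(-half, half, n_records) * 0.98
    lons = GridSpec.wrap_lon(lon_c + rng.uniform(-half, half, n_records) * 0.98)
    months = spec.month_values[imo]
    years = rng.integers(1955, 2016, n_records)
    days = rng.integers(1, 29, n_records)
    depth = np.abs(rng.normal(20.0, 15.0, n_records))
    net = np.clip(depth + np.abs(rng.normal(60.0, 40.0, n_records)), None, 480.0)
    sal = np.asarray(env["SSS"])[imo, ila, ilo] + rng.normal(0, 0.2, n_records)
    bathy = np.asarray(env["bathymetry"])[ila, ilo]

    df = pd.DataFrame(
        {
            "species_id": [species[i].id for i in isp],
            "decimal_longitude": lons,
            "decimal_latitude": lats,
            "year": years.astype(float),
            "month": months.astype(float),
            "day": days.astype(float),
            "depth_m": depth,
            "max_net_depth_m": net,
            "salinity_at_point": sal,
            "bathymetry_m": bathy,
            "source": "synthetic survey",
        }
    )

    n_bad = int(round(contamination * n_records))
    if n_bad > 0:
        bad_rows = rng.choice(n_records, size=n_bad, replace=False)
        for j, row in enumerate(bad_rows):
            kind = _CONTAMINATION_KINDS[j % len(_CONTAMINATION_KINDS)]
            if kind == "missing_coord":
                df.loc[row, "decimal_longitude"] = np.nan
            elif kind == "incomplete_date":
                df.loc[row, "day"] = np.nan
            elif kind == "pre1800":
                df.loc[row, "year"] = 1750.0
            elif kind == "missing_depth":
                df.loc[row, ["depth_m", "max_net_depth_m"]] = np.nan
            elif kind == "genus_only":
                df.loc[row, "species_id"] = str(df.loc[row, "species_id"]).split()[0]
            elif kind == "fossil_source":
                df.loc[row, "source"] = "sediment core ODP-893"
            elif kind == "low_salinity":
                df.loc[row, "salinity_at_point"] = 14.0
            elif kind == "shallow_bathymetry":
                df.loc[row, "bathymetry_m"] = 120.0
            elif kind == "deep_net":
                df.loc[row, "max_net_depth_m"] = 800.0
                df.loc[row, "depth_m"] = 600.0
    return df


# ---------------------------------------------------------------------------
# future anomalies
# ---------------------------------------------------------------------------
def generate_future_anomalies(
    env: xr.Dataset,
    esm_configs: list[ESMConfig],
    seed: int = 0,
) -> list[AnomalySet]:
    """One anomaly (delta) field set per pseudo-ESM.

    The SST delta is the configured amplitude shaped by the spatial pattern;
    the biogeochemical deltas respond proportionally to the local warming, so
    a zero-amplitude configuration propagates exact zeros everywhere.
    """
    if not esm_configs:
        raise ValueError("need at least one ESM config")
    spec: GridSpec = env.attrs["grid"]
    lat = spec.lat_centers[:, None] * np.ones((1, spec.n_lon))
    out = []
    for cfg in esm_configs:
        if cfg.pattern == "uniform":
            pattern = np.ones_like(lat)
        elif cfg.pattern == "polar":
            pattern = 0.6 + 0.8 * np.abs(lat) / 90.0
        else:
            raise ValueError(f"unknown anomaly pattern {cfg.pattern!r}")
        dsst2d = cfg.sst_amplitude * pattern
        months = env["month"].values
        dsst = np.broadcast_to(dsst2d, (len(months),) + dsst2d.shape).copy()
        coords = {"month": months, "lat": spec.lat_centers, "lon": spec.lon_centers}
        dims = ("month", "lat", "lon")

        def da(arr):
            return xr.DataArray(arr, coords=coords, dims=dims)

        deltas = {"SST": da(dsst)}
        for name, sens, mode in (
            ("NO3", cfg.nutrient_sensitivity, "frac"),
            ("PO4", cfg.nutrient_sensitivity, "frac"),
            ("SiOH4", cfg.nutrient_sensitivity, "frac"),
            ("Chl", cfg.chl_sensitivity, "frac"),
            ("MLD", cfg.mld_sensitivity, "frac"),
            ("dO2", cfg.do2_sensitivity, "abs"),
        ):
            if name not in env:
                continue
            base = np.asarray(env[name])
            if mode == "frac":
                delta = sens * dsst * base
                delta = np.clip(delta, -0.95 * base, None)  # keep fields positive
            else:
                delta = sens * dsst
                delta = np.clip(delta, -0.9 * base, None)
            deltas[name] = da(delta)
        ds = xr.Dataset(deltas)
        ds.attrs["grid"] = spec
        ds.attrs["esm_id"] = cfg.esm_id
        out.append(AnomalySet(esm_id=cfg.esm_id, deltas=ds))
    return out
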