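"""Diversity diagnostics: metabolic-theory temperature fits, range-shift
velocities, climate-impact severity regionalisation, trait-weighted
community size structure and ecosystem-service overlap tests.

The metabolic theory of ecology (MTE) predicts ln(richness) to be linear in
inverse thermal energy 1/(kT) with slopes near 0.32 eV for autotrophs and
0.65 eV for heterotrophs; the fit here regresses ln(SR) on 1/(kT) inside a
temperature window and also returns a cubic polynomial over the full range.

Range shifts are centroid displacements of the suitable habitat between the
present and future period midpoints (2021.5 and 2090.5, i.e. 6.9 decades),
measured with the haversine distance; centroids are computed per hemisphere
(on the hemisphere holding the larger suitability mass) so bipolar ranges
do not cancel to the equator.

Severity regionalisation standardises five diversity-change fields, takes
the leading principal components (enough for >=95% variance, at most four),
partitions the cells with k-medoids (PAM) on Euclidean PC distances, scores
each k by the Calinski-Harabasz index and silhouette, and summarises each
cell by the absolute variance-weighted sum of its PC scores (the severity
index).  Kruskal-Wallis tests with Bonferroni-corrected pairwise rank-sum
post hocs check whether gridded ecosystem-service covariates differ across
the resulting regions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "BOLTZMANN_EV",
    "MTEFit",
    "mte_fit",
    "haversine_km",
    "range_shift",
    "SeverityRegions",
    "severity_cluster",
    "pam_kmedoids",
    "weighted_median",
    "weighted_trait_structure",
    "service_overlap_tests",
]

BOLTZMANN_EV = 8.617333e-5  # eV / K
EARTH_RADIUS_KM = 6371.0


# ---------------------------------------------------------------------------
# MTE
# ---------------------------------------------------------------------------
@dataclass
class MTEFit:
    slope_ev: float  # magnitude of d ln(SR) / d[1/(kT)]
    slope_sign: int
    intercept: float
    r2: float
    poly3: np.ndarray  # highest degree first, over the full 1/(kT) range
    poly3_r2: float
    window: tuple
    n_cells: int


def mte_fit(sr, sst, window=(-2.0, 35.0), min_cells: int = 10) -> MTEFit:
    """OLS of ln(SR) on inverse thermal energy 1/(kT) inside an SST window.

    ``sr`` and ``sst`` are matching 2-D fields (annual means); only cells
    with SR > 0 enter the fit.  The cubic polynomial is fitted over all
    valid cells regardless of the window.
    """
    sr = np.asarray(sr, float).ravel()
    sst = np.asarray(sst, float).ravel()
    ok = np.isfinite(sr) & np.isfinite(sst) & (sr > 0)
    if not ok.any():
        raise ValueError("no valid cells for the MTE fit")
    x_all = 1.0 / (BOLTZMANN_EV * (sst[ok] + 273.15))
    y_all = np.log(sr[ok])
    t = sst[ok]
    in_win = (t >= window[0]) & (t <= window[1])
    if in_win.sum() < min_cells:
        raise ValueError(
            f"only {int(in_win.sum())} cells inside the window {window}"
        )
    x, y = x_all[in_win], y_all[in_win]
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = np.sum((y - yhat) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    poly3 = np.polyfit(x_all, y_all, 3)
    y3 = np.polyval(poly3, x_all)
    ss3 = np.sum((y_all - y3) ** 2)
    sst3 = np.sum((y_all - y_all.mean()) ** 2)
    return MTEFit(
        slope_ev=abs(float(slope)),
        slope_sign=int(np.sign(slope)) if slope != 0 else 0,
        intercept=float(intercept),
        r2=float(r2),
        poly3=poly3,
        poly3_r2=float(1.0 - ss3 / sst3) if sst3 > 0 else 1.0,
        window=tuple(window),
        n_cells=int(in_win.sum()),
    )


# ---------------------------------------------------------------------------
# range shifts
# ---------------------------------------------------------------------------
def haversine_km(lon1, lat1, lon2, lat2, radius: float = EARTH_RADIUS_KM):
    """Great-circle distance in km."""
    lon1, lat1, lon2, lat2 = map(np.deg2rad, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * radius * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def _weighted_centroid(hsi: np.ndarray, lat: np.ndarray, lon: np.ndarray, area_w):
    """HSI-weighted centroid (lon via circular mean to survive the date line)."""
    w = np.where(np.isfinite(hsi), hsi, 0.0) * area_w
    tot = w.sum()
    if tot <= 0:
        return np.nan, np.nan, 0.0
    lat2 = lat[:, None] * np.ones((1, len(lon)))
    lon2 = np.ones((len(lat), 1)) * lon[None, :]
    clat = float(np.sum(w * lat2) / tot)
    rad = np.deg2rad(lon2)
    clon = float(np.rad2deg(np.arctan2(np.sum(w * np.sin(rad)), np.sum(w * np.cos(rad)))))
    return clon, clat, float(tot)


def range_shift(
    present_hsi: xr.DataArray,
    future_hsi: xr.DataArray,
    period_midpoints=(2021.5, 2090.5),
) -> pd.DataFrame:
    """Centroid shifts of the suitable habitat per species.

    Input cubes have dims (species, lat, lon) (annual ensemble-mean HSI).
    The centroid is computed on the hemisphere holding the larger present
    suitability mass; ``poleward`` means the centroid's absolute latitude
    increased within that hemisphere.  Velocity is the haversine distance
    divided by the elapsed decades.  Species whose suitability is all zero
    are flagged with NaN rows.
    """
    lat = present_hsi["lat"].values
    lon = present_hsi["lon"].values
    area = np.cos(np.deg2rad(lat))[:, None]
    decades = (period_midpoints[1] - period_midpoints[0]) / 10.0
    north = lat >= 0

    rows = []
    for sp in present_hsi["species"].values:
        hp = np.asarray(present_hsi.sel(species=sp), float)
        hf = np.asarray(future_hsi.sel(species=sp), float)
        mass_n = np.nansum(np.where(north[:, None], hp, 0.0) * area)
        mass_s = np.nansum(np.where(~north[:, None], hp, 0.0) * area)
        if mass_n + mass_s <= 0:
            rows.append(
                {"species_id": sp, "lon_present": np.nan, "lat_present": np.nan,
                 "lon_future": np.nan, "lat_future": np.nan,
                 "distance_km": np.nan, "velocity_km_per_decade": np.nan,
                 "poleward": np.nan}
            )
            continue
        hemi = north if mass_n >= mass_s else ~north
        sel = hemi[:, None]
        p_lon, p_lat, _ = _weighted_centroid(np.where(sel, hp, 0.0), lat, lon, area)
        f_lon, f_lat, f_mass = _weighted_centroid(np.where(sel, hf, 0.0), lat, lon, area)
        if f_mass <= 0:
            f_lon, f_lat = p_lon, p_lat
        d = float(haversine_km(p_lon, p_lat, f_lon, f_lat))
        rows.append(
            {
                "species_id": sp,
                "lon_present": p_lon,
                "lat_present": p_lat,
                "lon_future": f_lon,
                "lat_future": f_lat,
                "distance_km": d,
                "velocity_km_per_decade": d / decades,
                "poleward": bool(abs(f_lat) > abs(p_lat)),
            }
        )
    df = pd.DataFrame(rows)
    ok = df["velocity_km_per_decade"].notna()
    pole = df.loc[ok & (df["poleward"] == True)]  # noqa: E712
    df.attrs["summary"] = {
        "n_species": int(ok.sum()),
        "frac_poleward": float((df.loc[ok, "poleward"] == True).mean()) if ok.any() else np.nan,  # noqa: E712
        "median_velocity_all": float(df.loc[ok, "velocity_km_per_decade"].median()) if ok.any() else np.nan,
        "std_velocity_all": float(df.loc[ok, "velocity_km_per_decade"].std()) if ok.any() else np.nan,
        "iqr_velocity_all": float(
            df.loc[ok, "velocity_km_per_decade"].quantile(0.75)
            - df.loc[ok, "velocity_km_per_decade"].quantile(0.25)
        ) if ok.any() else np.nan,
        "median_velocity_poleward": float(pole["velocity_km_per_decade"].median()) if len(pole) else np.nan,
    }
    return df


# ---------------------------------------------------------------------------
# k-medoids (PAM) and severity regionalisation
# ---------------------------------------------------------------------------
def pam_kmedoids(D: np.ndarray, k: int, seed: int = 0, max_iter: int = 100):
    """Partition-around-medoids on a precomputed distance matrix.

    Greedy BUILD initialisation followed by alternating assignment /
    medoid-update sweeps until the medoid set is stable.  Deterministic for
    a given distance matrix and seed (the seed only breaks exact ties).
    """
    n = D.shape[0]
    if not (1 <= k <= n):
        raise ValueError("k out of range")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0, 1e-12, n)  # deterministic tie-break
    medoids = [int(np.argmin(D.sum(axis=1) + jitter))]
    while len(medoids) < k:
        dmin = D[:, medoids].min(axis=1)
        gains = np.maximum(dmin[None, :] - D, 0).sum(axis=1) + jitter
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = np.array(sorted(medoids))
    for _ in range(max_iter):
        labels = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            idx = np.flatnonzero(labels == c)
            if idx.size == 0:
                continue
            sub = D[np.ix_(idx, idx)]
            new[c] = idx[int(np.argmin(sub.sum(axis=1)))]
        new = np.array(sorted(new))
        if np.array_equal(new, medoids):
            break
        medoids = new
    labels = np.argmin(D[:, medoids], axis=1)
    return labels, medoids


@dataclass
class SeverityRegions:
    labels: xr.DataArray  # region id (1..k), NaN off-mask
    severity: xr.DataArray
    k: int
    ch_profile: dict
    silhouette_profile: dict
    explained_variance_ratio: np.ndarray
    pc_weights: np.ndarray
    region_rank: pd.DataFrame  # regions ordered by decreasing median severity
    dropped_fields: list = field(default_factory=list)


def severity_cluster(
    change: xr.Dataset,
    k_range=range(2, 11),
    seed: int = 0,
    max_pcs: int = 4,
    variance_target: float = 0.95,
    k: int | None = None,
) -> SeverityRegions:
    """Regionalise the ocean by climate-impact severity.

    ``change`` holds the five diversity-change fields on a common mask.
    Fields are standardised; a PCA retains the leading components (up to
    ``max_pcs``, at least enough for ``variance_target`` of the variance);
    cells are partitioned with PAM on Euclidean PC distances for each k in
    ``k_range``; the final k maximises the Calinski-Harabasz index unless
    the user fixes ``k``.  The severity of a cell is the absolute value of
    the variance-share-weighted sum of its PC scores.
    """
    from sklearn.decomposition import PCA
    from sklearn.metrics import calinski_harabasz_score, silhouette_score

    names = list(change.data_vars)
    fields = []
    dropped = []
    for nme in names:
        arr = np.asarray(change[nme], float)
        if np.nanstd(arr) == 0:
            warnings.warn(f"change field {nme!r} is constant; dropped")
            dropped.append(nme)
        else:
            fields.append((nme, arr))
    if not fields:
        raise ValueError("all change fields are constant; clustering refused")
    stack = np.stack([a for _, a in fields])
    mask = np.all(np.isfinite(stack), axis=0)
    X = stack[:, mask].T
    X = (X - X.mean(axis=0)) / X.std(axis=0)

    pca = PCA(n_components=min(X.shape[1], max(max_pcs, 1)), random_state=seed)
    scores_full = pca.fit_transform(X)
    evr = pca.explained_variance_ratio_
    n_keep = min(max_pcs, len(evr))
    if evr[: n_keep].sum() < variance_target and n_keep < len(evr):
        n_keep = len(evr)
    scores = scores_full[:, :n_keep]
    weights = evr[:n_keep]

    from scipy.spatial.distance import squareform, pdist

    D = squareform(pdist(scores))
    ch, sil, labelings = {}, {}, {}
    for kk in k_range:
        if kk >= len(scores):
            continue
        lab, _ = pam_kmedoids(D, kk, seed=seed)
        labelings[kk] = lab
        ch[kk] = float(calinski_harabasz_score(scores, lab))
        sil[kk] = float(silhouette_score(D, lab, metric="precomputed"))
    if not ch:
        raise ValueError("no feasible k in k_range")
    k_final = k if k is not None else max(ch, key=ch.get)
    labels_flat = labelings[k_final] + 1

    sev_flat = np.abs(scores @ weights)
    lab_field = np.full(mask.shape, np.nan)
    sev_field = np.full(mask.shape, np.nan)
    lab_field[mask] = labels_flat
    sev_field[mask] = sev_flat
    coords = {"lat": change["lat"].values, "lon": change["lon"].values}
    lab_da = xr.DataArray(lab_field, coords=coords, dims=("lat", "lon"))
    sev_da = xr.DataArray(sev_field, coords=coords, dims=("lat", "lon"))

    med = (
        pd.DataFrame({"region": labels_flat, "severity": sev_flat})
        .groupby("region")["severity"]
        .agg(["median", "count"])
        .reset_index()
        .sort_values("median", ascending=False)
        .reset_index(drop=True)
    )
    med["rank"] = np.arange(1, len(med) + 1)
    return SeverityRegions(
        labels=lab_da,
        severity=sev_da,
        k=int(k_final),
        ch_profile=ch,
        silhouette_profile=sil,
        explained_variance_ratio=evr,
        pc_weights=weights,
        region_rank=med,
        dropped_fields=dropped,
    )


# ---------------------------------------------------------------------------
# trait-weighted size structure
# ---------------------------------------------------------------------------
def weighted_median(values, weights) -> float:
    """Weighted median with the midpoint convention at exact 0.5 splits."""
    v = np.asarray(values, float)
    w = np.asarray(weights, float)
    ok = np.isfinite(v) & np.isfinite(w) & (w > 0)
    v, w = v[ok], w[ok]
    if v.size == 0:
        return np.nan
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]
    cum = np.cumsum(w)
    half = 0.5 * cum[-1]
    i = int(np.searchsorted(cum, half, side="left"))
    if np.isclose(cum[i], half) and i + 1 < v.size:
        return 0.5 * (v[i] + v[i + 1])
    return float(v[i])


def resolve_traits(
    traits: pd.DataFrame,
    min_measurements: int = 5,
    sv_max: float = 10.0,
) -> pd.Series:
    """Per-species trait values with genus fallback and outlier removal.

    Species with fewer than ``min_measurements`` measurements inherit their
    genus mean; species with mean surface-to-volume ratio above ``sv_max``
    are treated as artifactual and excluded.
    """
    df = traits.copy()
    if "sv_ratio" in df:
        df = df[~(df["sv_ratio"] > sv_max)]
    if "genus" not in df:
        df["genus"] = df["species_id"].str.split().str[0]
    genus_mean = df.groupby("genus")["trait"].mean()
    n = df.get("n_measurements", pd.Series(min_measurements, index=df.index))
    use_genus = n < min_measurements
    vals = df["trait"].where(~use_genus, df["genus"].map(genus_mean))
    return pd.Series(vals.to_numpy(float), index=df["species_id"].to_numpy())


def _weighted_median_cube(trait_vals: np.ndarray, W: np.ndarray):
    """Vectorised weighted median along axis 0 (species) of weight array W.

    ``W`` has shape (n_species, ...); trait order must be ascending.
    """
    cum = np.cumsum(W, axis=0)
    tot = cum[-1]
    with np.errstate(invalid="ignore"):
        half = 0.5 * tot
        below = cum < half[None] - 1e-12
        idx = below.sum(axis=0)
    idx = np.clip(idx, 0, len(trait_vals) - 1)
    med = trait_vals[idx]
    exact = np.isclose(np.take_along_axis(cum, idx[None], axis=0)[0], half) & (
        idx + 1 < len(trait_vals)
    )
    nxt = trait_vals[np.clip(idx + 1, 0, len(trait_vals) - 1)]
    med = np.where(exact, 0.5 * (med + nxt), med)
    return np.where(tot > 0, med, np.nan)


def weighted_trait_structure(
    cube: xr.DataArray,
    traits: pd.DataFrame,
    future_cube: xr.DataArray | None = None,
    min_measurements: int = 5,
    sv_max: float = 10.0,
    min_coverage: float = 0.5,
) -> xr.Dataset:
    """HSI-weighted community trait structure (median and variance fields).

    Weights are the species' HSI.  Per member and month a weighted median
    across species is computed per cell, the annual value is the median
    over months, and the ensemble field averages members.  With a future
    cube the percentage change of the median field is added.
    """
    resolved = resolve_traits(traits, min_measurements, sv_max)
    species = [s for s in cube["species"].values.tolist() if s in resolved.index]
    if len(species) < min_coverage * cube.sizes["species"]:
        raise ValueError("insufficient trait coverage after genus fallback")
    vals = resolved.loc[species].to_numpy(float)
    order = np.argsort(vals, kind="stable")
    species_sorted = [species[i] for i in order]
    vals_sorted = vals[order]

    def _fields(c: xr.DataArray):
        W = np.asarray(c.sel(species=species_sorted), float)  # (member, sp, mo, la, lo)
        W = np.moveaxis(W, 1, 0)  # (sp, member, mo, la, lo)
        Wc = np.where(np.isfinite(W), W, 0.0)
        med = _weighted_median_cube(vals_sorted, Wc)  # (member, mo, la, lo)
        tot = Wc.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_w = np.tensordot(vals_sorted, Wc, axes=(0, 0)) / tot
            var_w = (
                np.tensordot(vals_sorted**2, Wc, axes=(0, 0)) / tot - mean_w**2
            )
        med_annual = np.nanmedian(med, axis=1)  # (member, la, lo)
        var_annual = np.nanmedian(var_w, axis=1)
        return np.nanmean(med_annual, axis=0), np.nanmean(var_annual, axis=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        med_p, var_p = _fields(cube)
    coords = {"lat": cube["lat"].values, "lon": cube["lon"].values}
    out = xr.Dataset(
        {
            "trait_median": xr.DataArray(med_p, coords=coords, dims=("lat", "lon")),
            "trait_variance": xr.DataArray(var_p, coords=coords, dims=("lat", "lon")),
        }
    )
    if future_cube is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            med_f, var_f = _fields(future_cube)
        out["trait_median_future"] = xr.DataArray(med_f, coords=coords, dims=("lat", "lon"))
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = 100.0 * (med_f - med_p) / np.where(med_p != 0, med_p, np.nan)
        out["trait_median_pct_change"] = xr.DataArray(pct, coords=coords, dims=("lat", "lon"))
    out.attrs["n_species_used"] = len(species)
    return out


# ---------------------------------------------------------------------------
# ecosystem-service overlap
# ---------------------------------------------------------------------------
def service_overlap_tests(
    regions: xr.DataArray,
    services: xr.Dataset,
    alpha: float = 0.01,
    exclude_regions: dict | None = None,
) -> dict:
    """Kruskal-Wallis across regions per service + Bonferroni post hocs.

    ``exclude_regions`` maps a service name to region ids left out of its
    test (e.g. a region without reliable reporting).  Constant services are
    skipped with a note.  Pairwise comparisons use two-sided rank-sum
    (Mann-Whitney) tests with Bonferroni multiplication by the number of
    pairs.
    """
    lab = np.asarray(regions, float).ravel()
    results = {}
    for name in services.data_vars:
        vals = np.asarray(services[name], float).ravel()
        ok = np.isfinite(lab) & np.isfinite(vals)
        sub_lab, sub_val = lab[ok], vals[ok]
        excl = set((exclude_regions or {}).get(name, ()))
        if excl:
            keep = ~np.isin(sub_lab, list(excl))
            sub_lab, sub_val = sub_lab[keep], sub_val[keep]
        region_ids = sorted(np.unique(sub_lab))
        groups = [sub_val[sub_lab == r] for r in region_ids]
        groups = [g for g in groups if len(g) >= 2]
        if len(groups) < 2:
            results[name] = {"skipped": "fewer than two usable regions"}
            continue
        if np.all(np.concatenate(groups) == np.concatenate(groups)[0]):
            results[name] = {"skipped": "constant service variable"}
            continue
        H, p = stats.kruskal(*groups)
        entry = {
            "kw_statistic": float(H),
            "kw_p": float(p),
            "significant": bool(p < alpha),
            "pairwise": [],
        }
        if p < alpha:
            pairs = [
                (region_ids[i], region_ids[j])
                for i in range(len(region_ids))
                for j in range(i + 1, len(region_ids))
            ]
            n_tests = len(pairs)
            for ri, rj in pairs:
                gi = sub_val[sub_lab == ri]
                gj = sub_val[sub_lab == rj]
                if len(gi) < 2 or len(gj) < 2:
                    continue
                stat, praw = stats.mannwhitneyu(gi, gj, alternative="two-sided")
                entry["pairwise"].append(
                    {
                        "region_a": int(ri),
                        "region_b": int(rj),
                        "p_raw": float(praw),
                        "p_bonferroni": float(min(1.0, praw * n_tests)),
                        "significant": bool(min(1.0, praw * n_tests) < alpha),
                    }
                )
        results[name] = entry
    return results
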