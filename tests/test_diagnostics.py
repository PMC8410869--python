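"""MTE fits, haversine/range shifts, PAM severity regions, trait medians,
service overlap tests."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from scipy import stats

from planksdm.diagnostics import (
    BOLTZMANN_EV,
    haversine_km,
    mte_fit,
    pam_kmedoids,
    range_shift,
    resolve_traits,
    service_overlap_tests,
    severity_cluster,
    weighted_median,
    weighted_trait_structure,
)


# ------------------------------------------------------------------- MTE
def _mte_world(slope, noise_sd=0.0, n=500, seed=0):
    rng = np.random.default_rng(seed)
    sst = rng.uniform(-2, 30, n)
    x = 1.0 / (BOLTZMANN_EV * (sst + 273.15))
    ln_sr = 5.0 - slope * x / 1.0
    # center the intercept so SR magnitudes stay reasonable
    ln_sr = ln_sr - ln_sr.mean() + 3.0
    if noise_sd:
        ln_sr = ln_sr + rng.normal(0, noise_sd, n)
    return np.exp(ln_sr), sst


def test_noiseless_slope_recovery_is_exact():
    sr, sst = _mte_world(0.65)
    fit = mte_fit(sr, sst)
    assert fit.slope_ev == pytest.approx(0.65, abs=1e-6)
    assert fit.r2 == pytest.approx(1.0, abs=1e-9)


def test_constant_richness_gives_zero_slope():
    sst = np.linspace(0, 30, 100)
    fit = mte_fit(np.full(100, 20.0), sst)
    assert fit.slope_ev == pytest.approx(0.0, abs=1e-9)


def test_window_restricts_the_fit():
    # different slopes below/above 15 degC; the window picks the warm branch
    rng = np.random.default_rng(1)
    sst = rng.uniform(0, 30, 2000)
    x = 1.0 / (BOLTZMANN_EV * (sst + 273.15))
    slope = np.where(sst > 15, 0.6, 0.2)
    ln_sr = 4.0 - slope * (x - x.mean())
    fit = mte_fit(np.exp(ln_sr), sst, window=(22.0, 35.0))
    assert fit.slope_ev == pytest.approx(0.6, abs=0.02)


def test_empty_window_raises():
    sr, sst = _mte_world(0.4)
    with pytest.raises(ValueError):
        mte_fit(sr, sst, window=(80.0, 90.0))


# -------------------------------------------------------------- distances
def law_of_cosines_km(lon1, lat1, lon2, lat2, R=6371.0):
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dl = np.deg2rad(lon2 - lon1)
    c = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return R * np.arccos(np.clip(c, -1, 1))


def test_haversine_against_law_of_cosines():
    rng = np.random.default_rng(3)
    for _ in range(100):
        lon1, lon2 = rng.uniform(-180, 180, 2)
        lat1, lat2 = rng.uniform(-89, 89, 2)
        assert abs(
            haversine_km(lon1, lat1, lon2, lat2)
            - law_of_cosines_km(lon1, lat1, lon2, lat2)
        ) < 0.1


def test_one_degree_of_latitude():
    d = haversine_km(10.0, 40.0, 10.0, 41.0)
    assert d == pytest.approx(111.195, abs=0.01)


# ------------------------------------------------------------ range shift
def _species_field(lat_center, lats, lons, breadth=8.0):
    field = np.exp(-0.5 * ((lats[:, None] - lat_center) / breadth) ** 2)
    return np.broadcast_to(field, (len(lats), len(lons))).copy()


def _hsi(speci, lats, lons):
    return xr.DataArray(
        np.stack(speci),
        coords={"species": [f"s{i}" for i in range(len(speci))],
                "lat": lats, "lon": lons},
        dims=("species", "lat", "lon"),
    )


def test_one_degree_centroid_shift_velocity():
    lats = np.arange(-89.5, 90, 1.0)
    lons = np.array([10.0])
    p = _hsi([_species_field(40.0, lats, lons, 0.3)], lats, lons)
    f = _hsi([_species_field(41.0, lats, lons, 0.3)], lats, lons)
    out = range_shift(p, f)
    row = out.iloc[0]
    assert row["distance_km"] == pytest.approx(111.195, abs=1.5)
    assert row["velocity_km_per_decade"] == pytest.approx(16.11, abs=0.3)
    assert bool(row["poleward"])


def test_identical_fields_zero_velocity():
    lats = np.arange(-85.0, 90, 10.0)
    lons = np.arange(-175.0, 180, 10.0)
    field = _species_field(20.0, lats, lons)
    out = range_shift(_hsi([field], lats, lons), _hsi([field], lats, lons))
    assert out["velocity_km_per_decade"].iloc[0] == pytest.approx(0.0, abs=1e-9)


def test_all_zero_suitability_flagged():
    lats = np.arange(-85.0, 90, 10.0)
    lons = np.arange(-175.0, 180, 10.0)
    zero = np.zeros((len(lats), len(lons)))
    out = range_shift(_hsi([zero], lats, lons), _hsi([zero], lats, lons))
    assert np.isnan(out["velocity_km_per_decade"].iloc[0])


def test_bipolar_species_uses_dominant_hemisphere():
    lats = np.arange(-89.5, 90, 1.0)
    lons = np.array([0.0])
    both = _species_field(45.0, lats, lons) + 0.5 * _species_field(-45.0, lats, lons)
    shifted = _species_field(47.0, lats, lons) + 0.5 * _species_field(-47.0, lats, lons)
    out = range_shift(_hsi([both], lats, lons), _hsi([shifted], lats, lons))
    assert out["lat_present"].iloc[0] > 30  # northern mass dominates
    assert bool(out["poleward"].iloc[0])


# ---------------------------------------------------------------- severity
def _blob_change(seed=0, n_side=16, separation=6.0):
    rng = np.random.default_rng(seed)
    n = n_side * n_side
    labels = (np.arange(n) % 2).astype(float)
    fields = {}
    for i in range(5):
        base = np.where(labels == 0, 0.0, separation * (1 if i % 2 else -1))
        fields[f"f{i}"] = (base + rng.normal(0, 1, n)).reshape(n_side, n_side)
    coords = {"lat": np.arange(n_side, dtype=float),
              "lon": np.arange(n_side, dtype=float)}
    ds = xr.Dataset(
        {k: xr.DataArray(v, coords=coords, dims=("lat", "lon"))
         for k, v in fields.items()}
    )
    return ds, labels.reshape(n_side, n_side)


def test_two_blobs_recovered_at_k2():
    from sklearn.metrics import adjusted_rand_score

    change, truth = _blob_change()
    regions = severity_cluster(change, k_range=range(2, 6), seed=0)
    assert regions.k == 2
    assert max(regions.ch_profile, key=regions.ch_profile.get) == 2
    ari = adjusted_rand_score(truth.ravel(), regions.labels.values.ravel())
    assert ari > 0.9


def test_constant_fields_refused():
    coords = {"lat": [0.0, 1.0], "lon": [0.0, 1.0]}
    flat = xr.Dataset(
        {f"f{i}": xr.DataArray(np.ones((2, 2)), coords=coords, dims=("lat", "lon"))
         for i in range(5)}
    )
    with pytest.raises(ValueError):
        with pytest.warns(UserWarning):
            severity_cluster(flat, k_range=range(2, 3), seed=0)


def test_severity_zero_at_field_mean():
    change, _ = _blob_change(seed=1)
    # plant a cell sitting exactly at the mean of every field
    for name in change.data_vars:
        arr = change[name].values
        arr[0, 0] = np.nan  # recomputed below
    means = {n: np.nanmean(change[n].values) for n in change.data_vars}
    for n in change.data_vars:
        change[n].values[0, 0] = means[n]
    regions = severity_cluster(change, k_range=range(2, 4), seed=0)
    # standardized coordinates ~0 -> PC scores ~0 -> severity ~0
    assert float(regions.severity.values[0, 0]) < np.nanmedian(regions.severity.values)


def test_pam_is_deterministic_and_partitions():
    rng = np.random.default_rng(5)
    X = np.r_[rng.normal(0, 1, (30, 2)), rng.normal(8, 1, (30, 2))]
    from scipy.spatial.distance import pdist, squareform

    D = squareform(pdist(X))
    l1, m1 = pam_kmedoids(D, 2, seed=0)
    l2, m2 = pam_kmedoids(D, 2, seed=0)
    np.testing.assert_array_equal(l1, l2)
    np.testing.assert_array_equal(m1, m2)
    assert len(np.unique(l1)) == 2
    assert (l1[:30] == l1[0]).all() and (l1[30:] == l1[30]).all()


# -------------------------------------------------------------- weighted
def test_weighted_median_conventions():
    assert weighted_median([1.0, 3.0], [0.5, 0.5]) == pytest.approx(2.0)
    assert weighted_median([7.0], [1.0]) == 7.0
    rng = np.random.default_rng(0)
    for n in (9, 10, 51):
        v = rng.normal(size=n)
        assert weighted_median(v, np.ones(n)) == pytest.approx(
            float(np.median(v)), abs=1e-12
        )
    # heavy weight pins the median
    assert weighted_median([1.0, 2.0, 50.0], [1.0, 1.0, 10.0]) == 50.0


def test_resolve_traits_genus_fallback_and_outliers():
    traits = pd.DataFrame(
        {
            "species_id": ["Genus alpha", "Genus beta", "Genus gamma", "Other one"],
            "trait": [10.0, 30.0, 999.0, 5.0],
            "n_measurements": [10, 2, 10, 10],
            "sv_ratio": [1.0, 1.0, 20.0, 1.0],
        }
    )
    out = resolve_traits(traits)
    assert "Genus gamma" not in out.index  # S/V > 10 outlier removed
    assert out["Genus beta"] == pytest.approx(20.0)  # genus mean of {10, 30}
    assert out["Genus alpha"] == 10.0


def test_trait_structure_two_species_equal_weights():
    cube = xr.DataArray(
        np.full((1, 2, 1, 1, 1), 0.6),
        coords={"member": ["GLM|p1"], "species": ["Genus one", "Genus two"],
                "month": [1], "lat": [0.0], "lon": [0.0]},
        dims=("member", "species", "month", "lat", "lon"),
    )
    traits = pd.DataFrame(
        {"species_id": ["Genus one", "Genus two"], "trait": [1.0, 3.0],
         "n_measurements": [9, 9], "sv_ratio": [1.0, 1.0]}
    )
    out = weighted_trait_structure(cube, traits)
    assert out["trait_median"].item() == pytest.approx(2.0)
    assert out["trait_variance"].item() == pytest.approx(1.0)  # var of {1,3}


def test_trait_structure_single_species():
    cube = xr.DataArray(
        np.full((1, 1, 1, 1, 1), 0.4),
        coords={"member": ["GLM|p1"], "species": ["Genus one"],
                "month": [1], "lat": [0.0], "lon": [0.0]},
        dims=("member", "species", "month", "lat", "lon"),
    )
    traits = pd.DataFrame(
        {"species_id": ["Genus one"], "trait": [7.0],
         "n_measurements": [9], "sv_ratio": [1.0]}
    )
    out = weighted_trait_structure(cube, traits)
    assert out["trait_median"].item() == 7.0


def test_trait_structure_pct_change_future():
    def cube_with(vals):
        arr = np.array(vals, float).reshape(1, 2, 1, 1, 1)
        return xr.DataArray(
            arr,
            coords={"member": ["GLM|p1"], "species": ["Genus big", "Genus small"],
                    "month": [1], "lat": [0.0], "lon": [0.0]},
            dims=("member", "species", "month", "lat", "lon"),
        )

    traits = pd.DataFrame(
        {"species_id": ["Genus big", "Genus small"], "trait": [100.0, 10.0],
         "n_measurements": [9, 9], "sv_ratio": [1.0, 1.0]}
    )
    present = cube_with([0.9, 0.1])   # big species dominates
    future = cube_with([0.1, 0.9])    # small species takes over
    out = weighted_trait_structure(present, traits, future_cube=future)
    assert out["trait_median"].item() == 100.0
    assert out["trait_median_future"].item() == 10.0
    assert out["trait_median_pct_change"].item() == pytest.approx(-90.0)


# ---------------------------------------------------------------- services
def _region_labels(n_cells, k, seed=0):
    rng = np.random.default_rng(seed)
    return rng.integers(1, k + 1, n_cells).astype(float)


def test_identical_service_not_significant():
    rng = np.random.default_rng(7)
    lab = _region_labels(400, 3)
    services = xr.Dataset(
        {"npp": xr.DataArray(rng.normal(size=400), dims=("cell",))}
    )
    regions = xr.DataArray(lab, dims=("cell",))
    out = service_overlap_tests(regions, services)
    assert not out["npp"]["significant"]


def test_shifted_region_detected_with_bonferroni():
    rng = np.random.default_rng(8)
    lab = np.repeat([1.0, 2.0, 3.0], 100)
    vals = rng.normal(size=300)
    vals[lab == 2] += 10.0  # one region shifted by 10 sigma
    services = xr.Dataset({"catch": xr.DataArray(vals, dims=("cell",))})
    out = service_overlap_tests(xr.DataArray(lab, dims=("cell",)), services)
    res = out["catch"]
    assert res["kw_p"] < 1e-6
    pairs = pd.DataFrame(res["pairwise"])
    assert len(pairs) == 3  # k(k-1)/2
    assert (pairs["p_bonferroni"] >= pairs["p_raw"] - 1e-15).all()
    with2 = pairs[(pairs["region_a"] == 2) | (pairs["region_b"] == 2)]
    assert with2["significant"].all()


def test_kw_statistic_matches_rank_oracle():
    g1 = np.array([1.0, 3.0, 5.0])
    g2 = np.array([2.0, 4.0, 6.0, 8.0])
    lab = np.r_[np.full(3, 1.0), np.full(4, 2.0)]
    vals = np.r_[g1, g2]
    # hand rank computation
    ranks = stats.rankdata(vals)
    n = len(vals)
    groups = [ranks[lab == 1], ranks[lab == 2]]
    H = 12.0 / (n * (n + 1)) * sum(len(g) * g.mean() ** 2 for g in groups) - 3 * (n + 1)
    services = xr.Dataset({"svc": xr.DataArray(vals, dims=("cell",))})
    out = service_overlap_tests(xr.DataArray(lab, dims=("cell",)), services)
    assert out["svc"]["kw_statistic"] == pytest.approx(H, abs=1e-10)


def test_region_exclusion_honored():
    rng = np.random.default_rng(9)
    lab = np.repeat([1.0, 2.0, 3.0], 50)
    vals = rng.normal(size=150)
    vals[lab == 3] += 50.0
    services = xr.Dataset({"fish": xr.DataArray(vals, dims=("cell",))})
    out = service_overlap_tests(
        xr.DataArray(lab, dims=("cell",)), services,
        exclude_regions={"fish": [3]},
    )
    assert not out["fish"]["significant"]  # the outlier region was excluded
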