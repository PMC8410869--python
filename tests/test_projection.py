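"""Delta method, HSI projection, richness stacking, change stats, MESS."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from planksdm.projection import (
    apply_delta,
    compute_mess,
    ensemble_change,
    future_predictor_stack,
    member_keys,
    project_hsi,
    stack_richness,
)
from planksdm.sdm import fit_sdm
from planksdm import synth
from tests.conftest import make_training_frame


def test_member_key_design_counts():
    algos = ("GLM", "GAM", "RF", "ANN")
    sets = ("p1", "p2", "p3", "p4")
    esms = tuple(f"esm{i}" for i in range(5))
    assert len(member_keys(algos, sets)) == 16
    future = member_keys(algos, sets, esms)
    assert len(future) == 80
    assert len(set(future)) == 80


def test_zero_delta_round_trip_is_bit_identical(env):
    fut = apply_delta(env, env, env)
    for name in env.data_vars:
        np.testing.assert_array_equal(fut[name].values, env[name].values)


def test_uniform_plus_three_delta(env):
    base = env.copy()
    future = env.copy()
    future["SST"] = future["SST"] + 3.0
    out = apply_delta(env, base, future)
    np.testing.assert_allclose((out["SST"] - env["SST"]).values, 3.0, atol=1e-12)


def test_grid_mismatch_raises(env, spec10):
    from planksdm.grids import GridSpec

    other = synth.generate_environment(GridSpec(cell_size=30.0), seed=0)
    with pytest.raises(ValueError):
        apply_delta(env, other, other)


def test_dsst_special_rule():
    """obs range 8, ESM baseline range 10, ESM future range 12 -> dSST 10."""
    def mk(lo, hi):
        sst = np.linspace(lo, hi, 12).reshape(12, 1, 1)
        base = dict(
            SST=sst, NO3=np.full_like(sst, 5.0), PO4=np.full_like(sst, 0.3),
            SiOH4=np.full_like(sst, 4.0), Chl=np.full_like(sst, 0.2),
        )
        return xr.Dataset(
            {
                k: xr.DataArray(
                    v, coords={"month": range(1, 13), "lat": [0.0], "lon": [0.0]},
                    dims=("month", "lat", "lon"),
                )
                for k, v in base.items()
            }
        )

    obs = mk(10.0, 18.0)       # range 8
    esm_base = mk(9.0, 19.0)   # range 10
    esm_fut = mk(10.0, 22.0)   # range 12
    stack = future_predictor_stack(obs, esm_baseline=esm_base, esm_future=esm_fut)
    assert stack["dSST"].isel(month=0).item() == pytest.approx(10.0)


def test_anomaly_path_matches_recomputed_range(env):
    (aset,) = synth.generate_future_anomalies(
        env, [synth.ESMConfig("u", sst_amplitude=3.0)]
    )
    stack = future_predictor_stack(env, anomalies=aset)
    # uniform warming leaves the seasonal range unchanged
    from planksdm.predictors import derive_predictors

    np.testing.assert_allclose(
        stack["dSST"].values, derive_predictors(env)["dSST"].values, atol=1e-9
    )


# ------------------------------------------------------------------ HSI
@pytest.fixture(scope="module")
def tiny_store(stack):
    names = ["SST", "logChl"]
    df = make_training_frame(n_presence=50, predictors=("SST", "logChl"),
                             signal=("SST",), center=18.0, breadth=4.0, seed=3)
    # move the noise column into the range of logChl values
    df["SST"] = df["SST"] * 4 + 15
    fitted = fit_sdm(df, "GLM", names, seed=0)
    return {("Testus examplei", "GLM", "p1"): [fitted]}, {"p1": tuple(names)}


def test_project_hsi_bounds_and_dims(tiny_store, stack):
    models, sets = tiny_store
    cube = project_hsi(models, stack, sets)
    assert cube.dims == ("member", "species", "month", "lat", "lon")
    assert list(cube["member"].values) == ["GLM|p1"]
    vals = cube.values
    assert np.nanmin(vals) >= 0.0 and np.nanmax(vals) <= 1.0


def test_project_hsi_esm_suffix(tiny_store, stack):
    models, sets = tiny_store
    cube = project_hsi(models, stack, sets, esm="esmX")
    assert list(cube["member"].values) == ["GLM|p1|esmX"]


# ------------------------------------------------------------------ SR
def _cube(vals, members, species):
    vals = np.asarray(vals, float)
    return xr.DataArray(
        vals,
        coords={"member": members, "species": species,
                "month": [1, 2], "lat": [0.0, 10.0], "lon": [0.0]},
        dims=("member", "species", "month", "lat", "lon"),
    )


def test_richness_constant_hsi():
    cube = _cube(np.full((1, 1, 2, 2, 1), 0.5), ["GLM|p1"], ["a"])
    sr = stack_richness(cube)
    assert float(sr["sr_ensemble"].max()) == pytest.approx(0.5)
    cube3 = _cube(np.ones((1, 3, 2, 2, 1)), ["GLM|p1"], ["a", "b", "c"])
    assert float(stack_richness(cube3)["sr_ensemble"].min()) == pytest.approx(3.0)


def test_richness_additive_over_disjoint_groups():
    rng = np.random.default_rng(0)
    cube = _cube(rng.uniform(size=(2, 4, 2, 2, 1)), ["GLM|p1", "RF|p1"],
                 ["a", "b", "c", "d"])
    full = stack_richness(cube)["sr_annual"]
    g1 = stack_richness(cube, ["a", "b"])["sr_annual"]
    g2 = stack_richness(cube, ["c", "d"])["sr_annual"]
    xr.testing.assert_allclose(full, g1 + g2)
    with pytest.raises(ValueError):
        stack_richness(cube, [])


def test_ensemble_mean_is_member_average():
    rng = np.random.default_rng(1)
    cube = _cube(rng.uniform(size=(2, 2, 2, 2, 1)), ["GLM|p1", "RF|p1"], ["a", "b"])
    sr = stack_richness(cube)
    xr.testing.assert_allclose(sr["sr_ensemble"], sr["sr_annual"].mean("member"))


# ------------------------------------------------------------------ change
def _sr_dataset(values, members):
    da = xr.DataArray(
        np.asarray(values, float).reshape(len(members), 1, 1),
        coords={"member": members, "lat": [0.0], "lon": [0.0]},
        dims=("member", "lat", "lon"),
    )
    return xr.Dataset({"sr_annual": da})


def test_change_sign_agreement_arithmetic():
    present = _sr_dataset([100.0], ["GLM|p1"])
    fut_members = [f"GLM|p1|e{i}" for i in range(4)]
    future = _sr_dataset([101.0, 101.0, 101.0, 99.0], fut_members)
    ch = ensemble_change(present, future)
    np.testing.assert_allclose(
        np.sort(ch["pct_dsr_member"].values.ravel()), [-1.0, 1.0, 1.0, 1.0]
    )
    assert ch["agreement"].item() == pytest.approx(0.75)
    assert ch["stipple"].item() == 0.0


def test_change_zero_future_equals_present():
    present = _sr_dataset([50.0], ["GLM|p1"])
    future = _sr_dataset([50.0, 50.0], ["GLM|p1|e1", "GLM|p1|e2"])
    ch = ensemble_change(present, future)
    assert ch["pct_dsr_mean"].item() == 0.0
    assert ch["pct_dsr_iqr"].item() == 0.0
    assert np.isnan(ch["agreement"].item())  # no signed members
    assert np.isnan(ch["stipple"].item())


def test_change_masks_low_present_richness():
    present = _sr_dataset([0.3], ["GLM|p1"])
    future = _sr_dataset([0.6], ["GLM|p1|e1"])
    ch = ensemble_change(present, future)
    assert np.isnan(ch["pct_dsr_mean"].item())


def test_variance_attribution_identifies_dominant_factor():
    algos = ("GLM", "RF")
    esms = ("e1", "e2")
    members = [f"{a}|p1|{e}" for a in algos for e in esms]
    # change depends only on the algorithm -> algorithm share ~1
    fut_vals = [110.0, 110.0, 90.0, 90.0]
    present = _sr_dataset([100.0, 100.0], ["GLM|p1", "RF|p1"])
    future = _sr_dataset(fut_vals, members)
    ch = ensemble_change(present, future)
    assert ch["var_share_algorithm"].item() == pytest.approx(1.0)
    assert ch["var_share_esm"].item() == pytest.approx(0.0, abs=1e-12)


# ------------------------------------------------------------------ MESS
def brute_mess_point(v, ref):
    ref = np.sort(ref)
    n = len(ref)
    f = 100.0 * np.sum(ref < v) / n
    vmin, vmax = ref[0], ref[-1]
    if f == 0:
        return 100.0 * (v - vmin) / (vmax - vmin)
    if f <= 50:
        return 2.0 * f
    if f < 100:
        return 2.0 * (100.0 - f)
    return 100.0 * (vmax - v) / (vmax - vmin)


def _point_stack(values: dict):
    return xr.Dataset(
        {
            k: xr.DataArray(
                np.asarray(v, float).reshape(1, 1, len(np.atleast_1d(v))),
                coords={"month": [1], "lat": [0.0],
                        "lon": np.arange(len(np.atleast_1d(v)), dtype=float)},
                dims=("month", "lat", "lon"),
            )
            for k, v in values.items()
        }
    )


def test_mess_branch_values():
    ref = pd.DataFrame({"SST": np.arange(1.0, 11.0)})  # even n: median 5.5
    stack = _point_stack({"SST": [5.5, 1.0, 0.0, 12.0]})
    out = compute_mess(ref, stack, ["SST"])
    vals = out["mess"].values.ravel()
    assert vals[0] == pytest.approx(100.0)  # at the median: f=50 -> 2*50
    assert vals[1] == pytest.approx(0.0)    # at the minimum
    assert vals[2] < 0                       # below the range: non-analog
    assert vals[3] < 0                       # above the range


def test_mess_sign_iff_out_of_range_property():
    rng = np.random.default_rng(42)
    for _ in range(50):
        ref = rng.normal(size=rng.integers(4, 40))
        pts = rng.normal(scale=2.0, size=12)
        stack = _point_stack({"X": pts})
        out = compute_mess(pd.DataFrame({"X": ref}), stack, ["X"])
        got = out["mess"].values.ravel()
        for v, g in zip(pts, got):
            assert g == pytest.approx(brute_mess_point(v, ref), abs=1e-9)
            out_of_range = v < ref.min() or v > ref.max()
            assert (g < 0) == out_of_range


def test_mess_min_over_predictors_and_driver():
    ref = pd.DataFrame({"A": np.arange(10.0), "B": np.arange(10.0)})
    stack = _point_stack({"A": [4.0], "B": [-5.0]})
    out = compute_mess(ref, stack, ["A", "B"])
    assert out["mess"].item() < 0
    assert out["driver"].item() == 1  # B drives the extrapolation


def test_mess_degenerate_reference_sentinel():
    ref = pd.DataFrame({"A": np.full(5, 2.0)})
    stack = _point_stack({"A": [2.0, 3.0]})
    with pytest.warns(UserWarning):
        out = compute_mess(ref, stack, ["A"])
    vals = out["mess"].values.ravel()
    assert vals[0] == 0.0
    assert vals[1] == pytest.approx(-1.0e4)
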