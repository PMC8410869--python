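"""Delta-method future climatologies, HSI projection, richness stacking,
ensemble change statistics and MESS extrapolation masks.

Future forcing is built by the anomaly (delta) method: the ESM-projected
future-minus-baseline difference is added to the observed climatology,
predictor by predictor and month by month.  The annual SST range (dSST) has
its own rule — its delta is the difference of the ESMs' annual ranges, added
to the observed range — because recomputing the range from delta-shifted
months would mix the ESM's seasonal-cycle bias into the observation-based
field.

Species richness is the sum of habitat suitability indices over species
("potential richness"), averaged over the months with data; the ensemble is
the mean over members (algorithm x predictor set, times ESM for the
future).  Per-cell change statistics include the member-wise percentage
richness change, its ensemble spread, the sign-agreement stipple mask and a
main-effect variance decomposition over the member factorial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .predictors import derive_predictors

__all__ = [
    "member_keys",
    "apply_delta",
    "apply_anomalies",
    "future_predictor_stack",
    "project_hsi",
    "stack_richness",
    "ensemble_change",
    "compute_mess",
]

MESS_SENTINEL = -1.0e4


def member_keys(algorithms, predictor_sets, esms=None) -> list:
    """Ensemble member labels: ``ALGO|set`` or ``ALGO|set|esm``."""
    if esms is None:
        return [f"{a}|{s}" for a in algorithms for s in predictor_sets]
    return [f"{a}|{s}|{e}" for a in algorithms for s in predictor_sets for e in esms]


def _check_grid(a: xr.Dataset, b: xr.Dataset):
    if (a.sizes.get("lat"), a.sizes.get("lon")) != (b.sizes.get("lat"), b.sizes.get("lon")):
        raise ValueError("climatologies are not on the same grid")
    if not np.allclose(a["lat"], b["lat"]) or not np.allclose(a["lon"], b["lon"]):
        raise ValueError("climatologies are not on the same grid")


def apply_delta(
    obs: xr.Dataset, esm_baseline: xr.Dataset, esm_future: xr.Dataset
) -> xr.Dataset:
    """future = obs + (esm_future - esm_baseline), per predictor and month."""
    _check_grid(obs, esm_baseline)
    _check_grid(obs, esm_future)
    out = obs.copy()
    for name in obs.data_vars:
        if name in esm_baseline and name in esm_future:
            out[name] = obs[name] + (esm_future[name] - esm_baseline[name])
    out.attrs.update(obs.attrs)
    return out


def apply_anomalies(obs: xr.Dataset, anomalies) -> xr.Dataset:
    """Add precomputed delta fields (an :class:`~planksdm.synth.AnomalySet`
    or plain Dataset of deltas) to the observed climatology."""
    deltas = getattr(anomalies, "deltas", anomalies)
    _check_grid(obs, deltas)
    out = obs.copy()
    for name in deltas.data_vars:
        if name in out:
            out[name] = out[name] + deltas[name]
    out.attrs.update(obs.attrs)
    return out


def future_predictor_stack(
    obs: xr.Dataset,
    esm_baseline: xr.Dataset | None = None,
    esm_future: xr.Dataset | None = None,
    anomalies=None,
    **derive_kwargs,
) -> xr.Dataset:
    """Full future predictor stack with the dSST special rule.

    Either pass an ESM baseline/future pair (explicit delta method) or a
    precomputed anomaly set.  Log variants are recomputed from the delta-
    shifted linear-scale fields.  With the ESM pair, the future dSST is
    ``dSST(obs) + [range(SST_esm_future) - range(SST_esm_baseline)]``; with
    plain anomalies the rule reduces to recomputing the range from the
    shifted months (the baseline of an anomaly set is the observation
    itself).
    """
    if anomalies is not None:
        future_base = apply_anomalies(obs, anomalies)
        return derive_predictors(future_base, **derive_kwargs)
    if esm_baseline is None or esm_future is None:
        raise ValueError("need either an anomaly set or an ESM baseline/future pair")
    future_base = apply_delta(obs, esm_baseline, esm_future)
    stack = derive_predictors(future_base, **derive_kwargs)
    range_obs = obs["SST"].max("month") - obs["SST"].min("month")
    range_base = esm_baseline["SST"].max("month") - esm_baseline["SST"].min("month")
    range_fut = esm_future["SST"].max("month") - esm_future["SST"].min("month")
    dsst = range_obs + (range_fut - range_base)
    stack["dSST"] = dsst.broadcast_like(stack["SST"]).transpose(*stack["SST"].dims)
    return stack


# ---------------------------------------------------------------------------
# projection & stacking
# ---------------------------------------------------------------------------
def project_hsi(
    models: dict,
    stack: xr.Dataset,
    predictor_sets: dict,
    esm: str | None = None,
) -> xr.DataArray:
    """Project a model store onto a predictor stack.

    ``models`` maps (species, algorithm, set) -> list of fitted models (the
    evaluation-split fits); their predictions are averaged.  Returns an HSI
    cube with dims (member, species, month, lat, lon); member labels gain a
    ``|esm`` suffix when ``esm`` is given.  Missing members are skipped with
    a warning.
    """
    from .sdm import _prediction_frames

    species = sorted({k[0] for k in models})
    algos = sorted({k[1] for k in models})
    sets = sorted({k[2] for k in models})
    members = [f"{a}|{s}" for a in algos for s in sets]
    frames = {s: _prediction_frames(stack, predictor_sets[s]) for s in sets}
    months = stack["month"].values
    arr = np.full(
        (len(members), len(species), len(months), stack.sizes["lat"], stack.sizes["lon"]),
        np.nan,
    )
    for i_m, member in enumerate(members):
        a, s = member.split("|")
        frame, valid, shape3 = frames[s]
        for i_sp, sp in enumerate(species):
            fits = models.get((sp, a, s))
            if not fits:
                warnings.warn(f"no fitted models for member {member} / {sp}")
                continue
            acc = np.zeros(len(frame))
            for f in fits:
                acc += f.predict(frame)
            full = np.full(valid.shape, np.nan)
            full[valid] = acc / len(fits)
            arr[i_m, i_sp] = full.reshape(shape3)
    labels = [f"{m}|{esm}" if esm else m for m in members]
    return xr.DataArray(
        arr,
        coords={"member": labels, "species": species, "month": months,
                "lat": stack["lat"].values, "lon": stack["lon"].values},
        dims=("member", "species", "month", "lat", "lon"),
        name="hsi",
    )


def stack_richness(cube: xr.DataArray, group=None) -> xr.Dataset:
    """Stack HSI into species richness fields.

    ``group`` restricts to a species subset (list of ids).  Monthly SR is
    the plain sum of HSI over species; the annual field averages the months
    with data; the ensemble field averages members.
    """
    if group is not None:
        group = list(group)
        if not group:
            raise ValueError("empty species group")
        cube = cube.sel(species=group)
    if cube.sizes["species"] == 0:
        raise ValueError("empty species group")
    sr_monthly = cube.sum("species", skipna=False)
    sr_annual = sr_monthly.mean("month", skipna=True)
    out = xr.Dataset(
        {
            "sr_monthly": sr_monthly,
            "sr_annual": sr_annual,
            "sr_ensemble": sr_annual.mean("member", skipna=True),
        }
    )
    return out


def _member_factors(members) -> pd.DataFrame:
    parts = [m.split("|") for m in members]
    df = pd.DataFrame(parts, columns=["algorithm", "predictor_set", "esm"][: len(parts[0])])
    df.index = list(members)
    return df


def ensemble_change(
    present: xr.Dataset,
    future: xr.Dataset,
    min_present_sr: float = 0.5,
    agreement_threshold: float = 0.9,
) -> xr.Dataset:
    """Per-cell ensemble statistics of the percentage richness change.

    Present members ``ALGO|set`` are matched to the future members
    ``ALGO|set|esm`` sharing their algorithm and predictor set.  Cells with
    present SR below ``min_present_sr`` are masked (division guard).  The
    sign-agreement fraction counts the majority sign among the non-zero
    member changes; the stipple flag marks agreement at or above the
    threshold.  Factor variance shares are main-effect sums of squares over
    the member factorial, reported as cell fields and a global summary.
    """
    pres = present["sr_annual"]
    fut = future["sr_annual"]
    fut_members = list(fut["member"].values)
    base_of = {m: "|".join(m.split("|")[:2]) for m in fut_members}
    pres_aligned = xr.concat(
        [pres.sel(member=base_of[m]) for m in fut_members], dim="member"
    ).assign_coords(member=fut_members)

    denom = pres_aligned.where(pres_aligned >= min_present_sr)
    pct = 100.0 * (fut - pres_aligned) / denom

    sign = np.sign(pct.where(pct != 0))
    n_signed = sign.notnull().sum("member")
    n_pos = (sign > 0).sum("member")
    n_neg = (sign < 0).sum("member")
    agreement = (xr.concat([n_pos, n_neg], dim="_s").max("_s") / n_signed).where(
        n_signed > 0
    )
    stipple = (agreement >= agreement_threshold).where(agreement.notnull())

    q1 = pct.quantile(0.25, dim="member").drop_vars("quantile")
    q3 = pct.quantile(0.75, dim="member").drop_vars("quantile")
    out = xr.Dataset(
        {
            "pct_dsr_member": pct,
            "pct_dsr_mean": pct.mean("member"),
            "pct_dsr_median": pct.median("member"),
            "pct_dsr_iqr": q3 - q1,
            "pct_dsr_std": pct.std("member"),
            "agreement": agreement,
            "stipple": stipple,
        }
    )

    # main-effect variance decomposition over the member factorial
    factors = _member_factors(fut_members)
    x = pct - pct.mean("member")
    ss_total = (x**2).sum("member")
    shares = {}
    for fac in factors.columns:
        ss = xr.zeros_like(ss_total)
        for level in factors[fac].unique():
            sel = [m for m in fut_members if factors.loc[m, fac] == level]
            mu = x.sel(member=sel).mean("member")
            ss = ss + len(sel) * mu**2
        shares[fac] = (ss / ss_total.where(ss_total > 0)).rename(f"var_share_{fac}")
        out[f"var_share_{fac}"] = shares[fac]
    summary = {
        f"var_share_{fac}": float(shares[fac].mean(skipna=True)) for fac in factors.columns
    }
    out.attrs["variance_shares_global"] = summary
    return out


# ---------------------------------------------------------------------------
# MESS
# ---------------------------------------------------------------------------
def compute_mess(
    reference: pd.DataFrame, stack: xr.Dataset, predictors
) -> xr.Dataset:
    """Multivariate environmental similarity of a projection stack to a
    species' reference envelope.

    Per predictor with value v and f = percentage of reference values below
    v: f=0 -> 100(v-min)/(max-min); f<=50 -> 2f; f<100 -> 2(100-f);
    f=100 -> 100(max-v)/(max-min).  The MESS is the minimum over predictors
    and is negative iff at least one predictor falls outside its reference
    range; the driver is the argmin predictor.  A degenerate predictor
    (max == min) scores 0 where v equals it and a large negative sentinel
    elsewhere.
    """
    predictors = list(predictors)
    months = stack["month"].values
    nlat, nlon = stack.sizes["lat"], stack.sizes["lon"]
    sims = np.full((len(predictors), len(months), nlat, nlon), np.nan)
    for i, name in enumerate(predictors):
        ref = np.sort(reference[name].dropna().to_numpy(float))
        if ref.size == 0:
            raise ValueError(f"empty reference for predictor {name!r}")
        arr = np.asarray(stack[name], float)
        if arr.ndim == 2:
            arr = np.broadcast_to(arr, (len(months), nlat, nlon))
        sims[i] = _mess_similarity(arr, ref, name)
    mess = np.nanmin(sims, axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        driver = np.nanargmin(
            np.where(np.isnan(sims), np.inf, sims), axis=0
        ).astype(float)
    driver[np.all(np.isnan(sims), axis=0)] = np.nan
    coords = {"month": months, "lat": stack["lat"].values, "lon": stack["lon"].values}
    dims = ("month", "lat", "lon")
    out = xr.Dataset(
        {
            "mess": xr.DataArray(mess, coords=coords, dims=dims),
            "driver": xr.DataArray(driver, coords=coords, dims=dims),
        }
    )
    out["mess_annual"] = out["mess"].mean("month", skipna=True)
    out.attrs["predictors"] = predictors
    return out


def _mess_similarity(values: np.ndarray, ref_sorted: np.ndarray, name: str) -> np.ndarray:
    n = ref_sorted.size
    vmin, vmax = ref_sorted[0], ref_sorted[-1]
    v = values
    if vmax == vmin:
        warnings.warn(f"degenerate reference range for {name!r}; sentinel applied")
        return np.where(v == vmin, 0.0, MESS_SENTINEL)
    f = 100.0 * np.searchsorted(ref_sorted, v, side="left") / n
    span = vmax - vmin
    sim = np.where(
        f == 0,
        100.0 * (v - vmin) / span,
        np.where(
            f <= 50,
            2.0 * f,
            np.where(f < 100, 2.0 * (100.0 - f), 100.0 * (vmax - v) / span),
        ),
    )
    return np.where(np.isnan(v), np.nan, sim)
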