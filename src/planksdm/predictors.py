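"""Derived predictors, collinearity screening and importance ranking.

The predictor stack extends the primary climatologies with the secondary
fields used for niche modelling:

* ``Nstar``  = NO3 - 16 * PO4 (nitrate excess over the Redfield ratio, uM)
* ``Sistar`` = SiOH4 - NO3 (silicic acid excess over nitrate, uM)
* ``dSST``   = annual SST range (warmest minus coldest month, per cell),
  replicated across months
* ``MLPAR``  = mean PAR over the mixed layer under exponential attenuation:
  PAR / (k * MLD) * (1 - exp(-k * MLD))
* ``EKE``    = 0.5 * (u'^2 + v'^2) from the eddy velocity components
* natural-log variants of the right-skewed fields (NO3, PO4, SiOH4, Chl,
  EKE), floored at a small positive value before logging.

Collinearity screening and per-species predictor ranking reproduce the
standard selection workflow: Spearman |rho| > 0.70 drops the member of a
pair farther from normality; importance is the absolute t-statistic for the
binomial GLM and the Gini impurity decrease for the random forest, with
ranks normalised to their maximum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

__all__ = [
    "PHYTO_SETS",
    "ZOO_SETS",
    "derive_predictors",
    "screen_collinearity",
    "CollinearityResult",
    "rank_predictors",
    "basin_balance_report",
    "match_predictors",
]

# The eight frozen predictor sets (p1..p4 per trophic group).
PHYTO_SETS = {
    "p1": ("SST", "dSST", "logChl", "Nstar", "PAR", "logNO3"),
    "p2": ("SST", "dSST", "logChl", "Nstar", "PAR", "logSiOH4"),
    "p3": ("SST", "dSST", "logChl", "Nstar", "PAR", "logNO3", "Sistar"),
    "p4": ("SST", "dSST", "logChl", "PAR", "logNO3"),
}
ZOO_SETS = {
    "p1": ("SST", "dSST", "dO2", "logChl", "logNO3"),
    "p2": ("SST", "dSST", "dO2", "logChl", "logSiOH4"),
    "p3": ("SST", "dSST", "dO2", "logChl", "logSiOH4", "Nstar"),
    "p4": ("SST", "dSST", "dO2", "logChl", "logNO3", "Sistar"),
}

_LOG_FIELDS = {"NO3": "logNO3", "PO4": "logPO4", "SiOH4": "logSiOH4", "Chl": "logChl"}


def derive_predictors(
    base: xr.Dataset,
    attenuation: float = 0.1,
    log_floor: float = 1e-6,
    log_base: str = "e",
) -> xr.Dataset:
    """Compute the secondary predictors from a primary climatology stack.

    Parameters
    ----------
    attenuation : float
        Light attenuation coefficient k (1/m) for the mixed-layer PAR.
    log_floor : float
        Values are clipped to this floor before logging; non-positive
        arguments therefore never produce -inf.
    log_base : {"e", "10"}
        Base of the log-variant fields (natural log by default).
    """
    for name in ("SST", "NO3", "PO4", "SiOH4", "Chl"):
        if name not in base:
            raise KeyError(f"primary field {name!r} missing from climatology")
    log = np.log if log_base == "e" else np.log10
    ds = base.copy()

    ds["Nstar"] = ds["NO3"] - 16.0 * ds["PO4"]
    ds["Sistar"] = ds["SiOH4"] - ds["NO3"]

    dsst = ds["SST"].max("month") - ds["SST"].min("month")
    ds["dSST"] = dsst.broadcast_like(ds["SST"]).transpose(*ds["SST"].dims)

    if "PAR" in ds and "MLD" in ds:
        kh = attenuation * ds["MLD"]
        ds["MLPAR"] = ds["PAR"] / kh * (1.0 - np.exp(-kh))
    if "uo" in ds and "vo" in ds:
        ds["EKE"] = 0.5 * (ds["uo"] ** 2 + ds["vo"] ** 2)

    for src, dst in _LOG_FIELDS.items():
        if src in ds:
            ds[dst] = xr.apply_ufunc(log, ds[src].clip(min=log_floor))
    if "EKE" in ds:
        ds["logEKE"] = xr.apply_ufunc(log, ds["EKE"].clip(min=log_floor))
    ds.attrs.update(base.attrs)
    return ds


def match_predictors(
    stack: xr.Dataset, points: pd.DataFrame, names=None
) -> pd.DataFrame:
    """Predictor values at (cell, month) points.

    ``points`` needs integer ``ilat``/``ilon`` and ``month`` columns; the
    result has one column per predictor, aligned with ``points``.
    """
    names = list(names) if names is not None else [
        v for v in stack.data_vars if "month" in stack[v].dims
    ]
    imo = points["month"].to_numpy(int) - int(stack["month"].values[0])
    ila = points["ilat"].to_numpy(int)
    ilo = points["ilon"].to_numpy(int)
    out = {}
    for name in names:
        arr = np.asarray(stack[name])
        if arr.ndim == 3:
            out[name] = arr[imo, ila, ilo]
        else:
            out[name] = arr[ila, ilo]
    return pd.DataFrame(out, index=points.index)


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------
@dataclass
class CollinearityResult:
    retained: list
    rho: pd.DataFrame
    dropped: list  # (dropped, kept, rho) tuples
    flagged_constant: list


def _normality_distance(x: np.ndarray) -> float:
    """Frozen tie-break metric: |skewness| + |excess kurtosis|."""
    return abs(stats.skew(x, nan_policy="omit")) + abs(
        stats.kurtosis(x, nan_policy="omit")
    )


def screen_collinearity(
    values: pd.DataFrame, threshold: float = 0.70
) -> CollinearityResult:
    """Drop one member of every predictor pair with Spearman |rho| > threshold.

    The member whose distribution is farther from normal (larger
    |skew| + |excess kurtosis|) is dropped.  Pairs are processed from the
    strongest correlation down, so the outcome does not depend on column
    order except through that frozen tie-break.  Constant predictors have
    undefined correlations; they are flagged and retained with a warning.
    """
    if len(values) < 3:
        raise ValueError("need at least 3 matched points")
    cols = list(values.columns)
    const = [c for c in cols if np.nanstd(values[c].to_numpy(float)) == 0]
    if const:
        warnings.warn(f"constant predictors retained without screening: {const}")
    active = [c for c in cols if c not in const]
    rho = values[active].corr(method="spearman") if active else pd.DataFrame()
    dist = {c: _normality_distance(values[c].to_numpy(float)) for c in active}

    pairs = []
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            pairs.append((abs(rho.loc[a, b]), a, b))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    retained = set(active)
    dropped = []
    for r, a, b in pairs:
        if r <= threshold:
            break
        if a in retained and b in retained:
            loser = a if dist[a] > dist[b] else b
            winner = b if loser == a else a
            retained.discard(loser)
            dropped.append((loser, winner, float(rho.loc[a, b])))
    keep = [c for c in cols if c in retained or c in const]
    full_rho = values.corr(method="spearman")
    return CollinearityResult(keep, full_rho, dropped, const)


# ---------------------------------------------------------------------------
# importance ranking
# ---------------------------------------------------------------------------
def rank_predictors(
    train_sets: dict,
    predictors,
    seed: int = 0,
    algorithms=("GLM", "RF"),
) -> pd.DataFrame:
    """Rank predictor importance per species for GLM and RF fits.

    For the GLM (binomial, linear + quadratic terms, no stepwise here), the
    importance of a predictor is the largest |t| among its terms; for the
    random forest it is the Gini importance.  Rank 1 is the most important
    predictor; ranks are divided by the maximum rank so the least important
    predictor of every fit scores 1.0.

    Parameters
    ----------
    train_sets : mapping species_id -> training DataFrame
        Each frame needs ``response``, ``weight`` and the predictor columns.
    """
    from .sdm import GLMConfig, RFConfig, _fit_glm_full, _fit_rf

    predictors = list(predictors)
    rows = []
    for k, (sp, df) in enumerate(sorted(train_sets.items())):
        y = df["response"].to_numpy(float)
        w = df["weight"].to_numpy(float)
        X = df[predictors].to_numpy(float)
        if "GLM" in algorithms:
            try:
                tvalues, _ = _fit_glm_full(X, y, w, GLMConfig())
                tvals = np.abs(np.asarray(tvalues))[1:]  # skip intercept
                imp = np.maximum(tvals[: len(predictors)], tvals[len(predictors):])
                rows += _rank_rows(sp, "GLM", predictors, imp)
            except Exception as exc:  # pragma: no cover - flagged, not fatal
                warnings.warn(f"GLM ranking failed for {sp}: {exc}")
        if "RF" in algorithms:
            rf = _fit_rf(X, y, w, RFConfig(), seed=seed + k)
            rows += _rank_rows(sp, "RF", predictors, rf.feature_importances_)
    out = pd.DataFrame(rows)
    return out


def _rank_rows(species, algorithm, predictors, importance):
    importance = np.asarray(importance, dtype=float)
    order = np.argsort(-importance, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(1, len(order) + 1)
    max_rank = ranks.max()
    return [
        {
            "species_id": species,
            "algorithm": algorithm,
            "predictor": p,
            "importance": float(importance[i]),
            "rank": int(ranks[i]),
            "norm_rank": float(ranks[i] / max_rank),
        }
        for i, p in enumerate(predictors)
    ]


def summarize_ranks(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Median normalised rank per predictor and algorithm."""
    return (
        rank_table.groupby(["algorithm", "predictor"])["norm_rank"]
        .median()
        .reset_index()
        .sort_values(["algorithm", "norm_rank"])
        .reset_index(drop=True)
    )


def basin_balance_report(
    values: pd.DataFrame, basin_labels: pd.Series
) -> pd.DataFrame:
    """Diagnostic for basin-imbalanced predictors.

    For every predictor and basin, reports the two-sample Kolmogorov-Smirnov
    distance between the basin's distribution at the presences and the
    pooled distribution; large distances flag predictors that act as basin
    indicators rather than environmental controls.  A report, not a filter.
    """
    rows = []
    for col in values.columns:
        pooled = values[col].dropna().to_numpy(float)
        for basin in sorted(basin_labels.dropna().unique()):
            sub = values.loc[basin_labels == basin, col].dropna().to_numpy(float)
            if len(sub) < 3:
                continue
            ks = stats.ks_2samp(sub, pooled).statistic
            rows.append({"predictor": col, "basin": basin, "ks_distance": float(ks)})
    return pd.DataFrame(rows)
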