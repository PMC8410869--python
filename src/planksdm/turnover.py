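"""Threshold-range binarisation and temporal Jaccard partitioning.

Mean-annual habitat suitability is converted to presence/absence over an
SDM-family-specific range of probability thresholds (0.25-0.40 for
GLM/GAM/ANN, 0.10-0.25 for RF, in 0.01 steps; presence at HSI >= t), and
the temporal dissimilarity between the present and future assemblage of a
cell is partitioned (Baselga family) into:

* total Jaccard dissimilarity  beta_jac = (b + c) / (a + b + c)
* true turnover (replacement)  beta_jtu = 2 min(b,c) / (a + 2 min(b,c))
* nestedness (richness change) beta_jne = beta_jac - beta_jtu

with a = shared species, b/c = exclusive species.  The partition is exact:
the two components always sum to the total.  A cell whose assemblage is
entirely replaced by an equal number of different species has beta_jtu = 1
(100% turnover) and beta_jne = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

__all__ = [
    "ThresholdPolicy",
    "DEFAULT_POLICY",
    "binarize",
    "jaccard_decompose",
    "JaccardDecomposition",
    "decompose_counts",
    "turnover_ensemble",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Per-algorithm [lo, hi] threshold ranges, stepped by 0.01."""

    ranges: tuple = (
        ("GLM", 0.25, 0.40),
        ("GAM", 0.25, 0.40),
        ("ANN", 0.25, 0.40),
        ("RF", 0.10, 0.25),
    )
    step: float = 0.01

    def __post_init__(self):
        for algo, lo, hi in self.ranges:
            if not (0.0 < lo < hi < 1.0):
                raise ValueError(f"invalid threshold range for {algo}")

    def range_of(self, algorithm: str) -> tuple:
        for algo, lo, hi in self.ranges:
            if algo == algorithm:
                return lo, hi
        raise KeyError(f"no threshold range for algorithm {algorithm!r}")

    def thresholds(self, algorithm: str) -> np.ndarray:
        lo, hi = self.range_of(algorithm)
        n = int(round((hi - lo) / self.step))
        return lo + self.step * np.arange(n + 1)


DEFAULT_POLICY = ThresholdPolicy()


def binarize(
    annual_hsi: xr.DataArray,
    threshold: float,
    algorithm: str | None = None,
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> xr.DataArray:
    """Presence iff mean annual HSI >= threshold.

    When ``algorithm`` is given the threshold must lie inside that family's
    range (inclusive), else a ValueError is raised.
    """
    if algorithm is not None:
        lo, hi = policy.range_of(algorithm)
        if not (lo - 1e-9 <= threshold <= hi + 1e-9):
            raise ValueError(
                f"threshold {threshold} outside the {algorithm} range [{lo}, {hi}]"
            )
    return (annual_hsi >= threshold).where(annual_hsi.notnull())


@dataclass(frozen=True)
class JaccardDecomposition:
    a: int
    b: int
    c: int

    @property
    def beta_jac(self) -> float:
        tot = self.a + self.b + self.c
        return (self.b + self.c) / tot if tot else 0.0

    @property
    def beta_jtu(self) -> float:
        m = min(self.b, self.c)
        denom = self.a + 2 * m
        return 2 * m / denom if denom else 0.0

    @property
    def beta_jne(self) -> float:
        return self.beta_jac - self.beta_jtu


def jaccard_decompose(present_set, future_set) -> JaccardDecomposition:
    """Partition the temporal dissimilarity between two assemblages.

    Accepts any iterables of species identifiers; empty vs empty yields all
    components 0 by convention.
    """
    p, f = set(present_set), set(future_set)
    return JaccardDecomposition(a=len(p & f), b=len(p - f), c=len(f - p))


def decompose_counts(a, b, c):
    """Vectorised decomposition from shared/exclusive count arrays."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    c = np.asarray(c, float)
    tot = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        jac = np.where(tot > 0, (b + c) / tot, 0.0)
        m = np.minimum(b, c)
        denom = a + 2 * m
        jtu = np.where(denom > 0, 2 * m / denom, 0.0)
    jne = jac - jtu
    return jac, jtu, jne


def turnover_ensemble(
    present_cube: xr.DataArray,
    future_cube: xr.DataArray,
    policy: ThresholdPolicy = DEFAULT_POLICY,
    groups: dict | None = None,
) -> xr.Dataset:
    """Ensemble-mean turnover fields.

    For every future member (matched to the present member sharing its
    algorithm and predictor set) and every threshold in the member's
    algorithm range, the annual-mean HSI of both periods is binarised and
    the per-cell Jaccard partition computed; the fields are then averaged
    over members and thresholds.  ``groups`` (name -> species list) yields
    one set of output variables per group; default is all species pooled.
    """
    ann_p = present_cube.mean("month", skipna=True)
    ann_f = future_cube.mean("month", skipna=True)
    fut_members = list(ann_f["member"].values)
    groups = groups or {"all": list(present_cube["species"].values)}

    out = {}
    for gname, sp_list in groups.items():
        gp = ann_p.sel(species=sp_list)
        gf = ann_f.sel(species=sp_list)
        acc = {k: [] for k in ("st", "jne", "jac")}
        for m in fut_members:
            algo = m.split("|")[0]
            base = "|".join(m.split("|")[:2])
            hp = gp.sel(member=base)
            hf = gf.sel(member=m)
            valid = hp.notnull().all("species") & hf.notnull().all("species")
            for t in policy.thresholds(algo):
                bp = np.asarray(hp >= t)
                bf = np.asarray(hf >= t)
                a = (bp & bf).sum(axis=0).astype(float)
                b = (bp & ~bf).sum(axis=0).astype(float)
                c = (~bp & bf).sum(axis=0).astype(float)
                jac, jtu, jne = decompose_counts(a, b, c)
                mask = np.asarray(valid)
                acc["st"].append(np.where(mask, jtu, np.nan))
                acc["jne"].append(np.where(mask, jne, np.nan))
                acc["jac"].append(np.where(mask, jac, np.nan))
        coords = {"lat": present_cube["lat"].values, "lon": present_cube["lon"].values}
        for key, stack_list in acc.items():
            arr = np.stack(stack_list)
            out[f"{key}_{gname}_mean"] = xr.DataArray(
                np.nanmean(arr, axis=0), coords=coords, dims=("lat", "lon")
            )
            out[f"{key}_{gname}_std"] = xr.DataArray(
                np.nanstd(arr, axis=0), coords=coords, dims=("lat", "lon")
            )
    return xr.Dataset(out)
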