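"""Signed log-likelihood-ratio species association networks.

Every pair of species is scored on its 2x2 co-occurrence table over grid
cells with the Dunning G² statistic,

    G² = 2 * sum_ij k_ij * ln( k_ij * N / (k_i. * k_.j) ),  0*ln 0 = 0,

equivalently ``2N [H(rows) + H(cols) - H(cells)]`` with H the Shannon
entropy.  The score is made negative when the observed co-occurrence count
falls below its independence expectation ``k_1. * k_.1 / N`` (species that
avoid each other), so the sign separates positive from negative
association.  Within a scenario, only pairs whose LLR exceeds the 75th
percentile of the positive scores are deemed significant; present and
future interactomes are compared member-by-member to count constant, lost
and gained associations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import xlogy

__all__ = [
    "ContingencyTable",
    "contingency",
    "llr_score",
    "pairwise_llr",
    "significant_pairs",
    "compare_interactomes",
    "interactome_change_ensemble",
]


@dataclass(frozen=True)
class ContingencyTable:
    k11: int  # both present
    k12: int  # A only
    k21: int  # B only
    k22: int  # neither

    @property
    def n(self) -> int:
        return self.k11 + self.k12 + self.k21 + self.k22

    @property
    def margins(self):
        r1 = self.k11 + self.k12
        r2 = self.k21 + self.k22
        c1 = self.k11 + self.k21
        c2 = self.k12 + self.k22
        return r1, r2, c1, c2


def contingency(a_present, b_present) -> ContingencyTable:
    """Exact 2x2 table from two aligned boolean presence vectors."""
    a = np.asarray(a_present, bool)
    b = np.asarray(b_present, bool)
    if a.shape != b.shape:
        raise ValueError("presence vectors must share the same cell universe")
    return ContingencyTable(
        k11=int(np.sum(a & b)),
        k12=int(np.sum(a & ~b)),
        k21=int(np.sum(~a & b)),
        k22=int(np.sum(~a & ~b)),
    )


def llr_score(t: ContingencyTable) -> float:
    """Signed G² of a 2x2 table; 0 when a margin is empty."""
    n = t.n
    if n == 0:
        raise ValueError("empty contingency table")
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        return 0.0
    ks = np.array([t.k11, t.k12, t.k21, t.k22], float)
    exp = np.array([r1 * c1, r1 * c2, r2 * c1, r2 * c2], float) / n
    g2 = 2.0 * float(np.sum(xlogy(ks, ks / exp)))
    g2 = max(g2, 0.0)  # clip tiny negative round-off
    if t.k11 < r1 * c1 / n:
        return -g2
    return g2


def pairwise_llr(presence: np.ndarray, species_ids, scenario: str = "") -> pd.DataFrame:
    """All-pairs signed LLR from a (species x cells) boolean matrix.

    Fully vectorised (the all-pairs score is evaluated once per ensemble
    member and threshold, so it sits on the pipeline's hot path).  Pairs
    involving a species present everywhere or nowhere have a zero margin
    and score 0 (they are removed later by the positivity rule).
    """
    P = np.asarray(presence, bool)
    n_sp, n_cells = P.shape
    Pf = P.astype(float)
    k11 = Pf @ Pf.T
    r = Pf.sum(axis=1)
    k12 = r[:, None] - k11
    k21 = r[None, :] - k11
    k22 = n_cells - k11 - k12 - k21
    n = float(n_cells)
    ra, rb = r[:, None], r[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        g2 = 2.0 * (
            xlogy(k11, k11 * n / (ra * rb))
            + xlogy(k12, k12 * n / (ra * (n - rb)))
            + xlogy(k21, k21 * n / ((n - ra) * rb))
            + xlogy(k22, k22 * n / ((n - ra) * (n - rb)))
        )
    g2 = np.maximum(np.nan_to_num(g2, nan=0.0), 0.0)
    zero_margin = (ra == 0) | (ra == n) | (rb == 0) | (rb == n)
    g2 = np.where(zero_margin, 0.0, g2)
    sign = np.where(k11 < ra * rb / n, -1.0, 1.0)
    llr = sign * g2
    iu, ju = np.triu_indices(n_sp, k=1)
    ids = np.asarray(species_ids, dtype=object)
    return pd.DataFrame(
        {
            "species_a": ids[iu],
            "species_b": ids[ju],
            "llr": llr[iu, ju],
            "scenario": scenario,
        }
    )


def significant_pairs(scores: pd.DataFrame, percentile: float = 75.0):
    """Pairs whose LLR strictly exceeds the Q75 of the positive scores.

    The percentile (linear interpolation) is computed per call — i.e. per
    scenario/member.  With no positive score the set is empty (warned); a
    single positive score can never exceed itself and is flagged degenerate.
    """
    pos = scores.loc[scores["llr"] > 0, "llr"].to_numpy(float)
    if pos.size == 0:
        warnings.warn("no positive LLR scores; empty association set")
        return set()
    if pos.size == 1:
        warnings.warn("single positive LLR score; degenerate percentile rule")
    q = np.percentile(pos, percentile)
    keep = scores.loc[scores["llr"] > q]
    return {
        frozenset((a, b)) for a, b in zip(keep["species_a"], keep["species_b"])
    }


def compare_interactomes(present: set, future: set) -> dict:
    """Constant / lost / gained association counts and fractions.

    Fractions are relative to the union of the two interactomes.
    """
    constant = present & future
    lost = present - future
    gained = future - present
    union = len(present | future)
    frac = (lambda k: k / union if union else 0.0)
    return {
        "constant": len(constant),
        "lost": len(lost),
        "gained": len(gained),
        "constant_frac": frac(len(constant)),
        "lost_frac": frac(len(lost)),
        "gained_frac": frac(len(gained)),
    }


def _annual_presence(cube: xr.DataArray, member, threshold: float):
    ann = cube.sel(member=member).mean("month", skipna=True)
    arr = np.asarray(ann)
    flat = arr.reshape(arr.shape[0], -1)
    valid = np.all(np.isfinite(flat), axis=0)
    return flat[:, valid] >= threshold


def interactome_change_ensemble(
    present_cube: xr.DataArray,
    future_cube: xr.DataArray,
    policy,
    percentile: float = 75.0,
    pair_filter=None,
) -> pd.DataFrame:
    """Median (± IQR) interactome change across members and thresholds.

    For every future member and threshold in its algorithm's range, the
    present and future annual assemblages are binarised, scored, thresholded
    at the per-scenario Q75 and compared.  ``pair_filter(species_a,
    species_b) -> bool`` restricts the comparison (e.g. to cross-trophic
    pairs) after scoring.  Returns the per-combination table; summary
    quantiles are in ``.attrs["summary"]``.
    """
    species = list(present_cube["species"].values)
    fut_members = list(future_cube["member"].values)
    rows = []
    for m in fut_members:
        algo = m.split("|")[0]
        base = "|".join(m.split("|")[:2])
        for t in policy.thresholds(algo):
            bp = _annual_presence(present_cube, base, t)
            bf = _annual_presence(future_cube, m, t)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sp_p = significant_pairs(
                    pairwise_llr(bp, species, scenario=f"present|{base}|{t:.2f}"),
                    percentile,
                )
                sp_f = significant_pairs(
                    pairwise_llr(bf, species, scenario=f"future|{m}|{t:.2f}"),
                    percentile,
                )
            if pair_filter is not None:
                sp_p = {p for p in sp_p if pair_filter(*sorted(p))}
                sp_f = {p for p in sp_f if pair_filter(*sorted(p))}
            rows.append(
                {"member": m, "threshold": t, **compare_interactomes(sp_p, sp_f)}
            )
    df = pd.DataFrame(rows)
    summary = {}
    for col in ("constant_frac", "lost_frac", "gained_frac"):
        summary[col] = {
            "median": float(df[col].median()),
            "q25": float(df[col].quantile(0.25)),
            "q75": float(df[col].quantile(0.75)),
        }
    df.attrs["summary"] = summary
    return df
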