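"""End-to-end synthetic-world pipeline.

Chains every stage on a synthetic world with known ground truth: generate
environment and species, sample biased occurrences, run QC / deduplication
/ binning, derive predictors, draw stratified target-group backgrounds, fit
the four-family SDM ensemble with ten 80/20 evaluation splits, project
present and per-pseudo-ESM future suitability, and compute richness change,
turnover, association-network change and the range-shift summary.

The default problem size (10-degree cells, 50 species, 2 pseudo-ESMs) keeps
a complete run within minutes on a single core while exercising every code
path at the full design (4 algorithms x 4 predictor sets x 10 splits).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import synth
from .grids import GridSpec
from .occurrences import QCRules, bin_to_grid, deduplicate, filter_occurrences
from .predictors import PHYTO_SETS, ZOO_SETS, derive_predictors
from .ensemble import PlanktonSDMEnsemble
from .projection import ensemble_change, future_predictor_stack, stack_richness
from .turnover import DEFAULT_POLICY, turnover_ensemble
from .associations import interactome_change_ensemble
from .diagnostics import mte_fit, range_shift

__all__ = ["PipelineResult", "run_synthetic_pipeline", "DEFAULT_PREDICTOR_SETS"]

# A trophic-agnostic predictor-set ensemble for the synthetic world: the
# phytoplankton p1/p4 and zooplankton p1/p4 sets (the synthetic niches are
# defined on SST, so every set contains the thermal axis).
DEFAULT_PREDICTOR_SETS = {
    "p1": PHYTO_SETS["p1"],
    "p2": PHYTO_SETS["p4"],
    "p3": ZOO_SETS["p1"],
    "p4": ZOO_SETS["p4"],
}


@dataclass
class PipelineResult:
    spec: GridSpec
    species: list
    filter_report: object
    presences: object
    skill: pd.DataFrame
    retained: list
    hsi: dict
    sr: dict
    change: xr.Dataset
    turnover: xr.Dataset
    associations: pd.DataFrame | None
    shifts: pd.DataFrame
    mte: object
    timings: dict = field(default_factory=dict)


def run_synthetic_pipeline(
    seed: int = 0,
    spec: GridSpec | None = None,
    n_species: int = 50,
    n_records: int = 20000,
    contamination: float = 0.05,
    esm_configs=None,
    predictor_sets=None,
    algorithms=("GLM", "GAM", "RF", "ANN"),
    n_splits: int = 10,
    min_presences: int = 75,
    with_associations: bool = True,
    effort: xr.DataArray | None = None,
) -> PipelineResult:
    """Run the complete pipeline on a synthetic world.

    Returns a :class:`PipelineResult` with every intermediate needed by the
    verification suite (skill table, retained species, suitability cubes,
    richness-change, turnover and association summaries, range shifts and
    the temperature-richness fit).
    """
    spec = spec or GridSpec(cell_size=10.0)
    if esm_configs is None:
        esm_configs = [
            synth.ESMConfig("ESM-warm", sst_amplitude=3.0, pattern="uniform"),
            synth.ESMConfig("ESM-mild", sst_amplitude=1.5, pattern="polar"),
        ]
    predictor_sets = predictor_sets or DEFAULT_PREDICTOR_SETS
    timings = {}
    t0 = time.time()

    # --- synthetic world -------------------------------------------------
    env = synth.generate_environment(spec, seed)
    species = synth.generate_species(n_species, env, seed + 1)
    eff = effort if effort is not None else synth.biased_effort(spec)
    raw = synth.sample_occurrences(
        species, env, eff, n_records, seed + 2, contamination=contamination
    )
    timings["synthesis"] = time.time() - t0

    # --- occurrences ------------------------------------------------------
    t0 = time.time()
    clean, report = filter_occurrences(raw, QCRules.zooplankton())
    clean = deduplicate(clean)
    presences = bin_to_grid(clean, spec)
    timings["occurrences"] = time.time() - t0

    # --- predictors & futures --------------------------------------------
    t0 = time.time()
    stack = derive_predictors(env)
    anomalies = synth.generate_future_anomalies(env, esm_configs, seed + 3)
    future_stacks = {
        a.esm_id: future_predictor_stack(env, anomalies=a) for a in anomalies
    }
    timings["predictors"] = time.time() - t0

    # --- SDM ensemble (streamed projection) -------------------------------
    t0 = time.time()
    model = PlanktonSDMEnsemble(
        presences,
        stack,
        predictor_sets,
        algorithms=algorithms,
        min_presences=min_presences,
    )
    results = model.fit(
        n_splits=n_splits,
        seed=seed + 4,
        climatologies={"present": stack, **future_stacks},
        store_models=False,
    )
    retained = results.select_species(min_presences=min_presences)
    timings["sdm"] = time.time() - t0

    # --- assemble present / future cubes for retained species -------------
    t0 = time.time()
    hsi_present = results.hsi["present"].sel(species=retained)
    fut_cubes = []
    for esm_id in future_stacks:
        c = results.hsi[esm_id].sel(species=retained)
        c = c.assign_coords(member=[f"{m}|{esm_id}" for m in c["member"].values])
        fut_cubes.append(c)
    hsi_future = xr.concat(fut_cubes, dim="member")
    hsi = {"present": hsi_present, "future": hsi_future}

    sp_by_id = {sp.id: sp for sp in species}
    groups = {
        "all": retained,
        "phyto": [s for s in retained if sp_by_id[s].trophic_group == "phyto"],
        "zoo": [s for s in retained if sp_by_id[s].trophic_group == "zoo"],
    }
    groups = {k: v for k, v in groups.items() if v}

    sr = {
        "present": stack_richness(hsi_present),
        "future": stack_richness(hsi_future),
    }
    change = ensemble_change(sr["present"], sr["future"])
    turn = turnover_ensemble(hsi_present, hsi_future, DEFAULT_POLICY, groups=groups)
    timings["projection"] = time.time() - t0

    t0 = time.time()
    assoc = None
    if with_associations:
        assoc = interactome_change_ensemble(hsi_present, hsi_future, DEFAULT_POLICY)
    timings["associations"] = time.time() - t0

    # --- diagnostics -------------------------------------------------------
    t0 = time.time()
    shifts = range_shift(
        hsi_present.mean("member", skipna=True).mean("month", skipna=True),
        hsi_future.mean("member", skipna=True).mean("month", skipna=True),
    )
    sst_annual = stack["SST"].mean("month")
    mte = mte_fit(
        np.asarray(sr["present"]["sr_ensemble"]), np.asarray(sst_annual)
    )
    timings["diagnostics"] = time.time() - t0

    return PipelineResult(
        spec=spec,
        species=species,
        filter_report=report,
        presences=presences,
        skill=results.skill,
        retained=retained,
        hsi=hsi,
        sr=sr,
        change=change,
        turnover=turn,
        associations=assoc,
        shifts=shifts,
        mte=mte,
        timings=timings,
    )
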