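"""Model/Results interface over the SDM ensemble.

:class:`PlanktonSDMEnsemble` is constructed from gridded presences and a
predictor stack (statsmodels-style: the model holds the data and design,
``fit`` does the work and returns a results object).  The results object
carries the skill table, the per-species retention decision, the model
store and/or streamed habitat-suitability cubes, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
import xarray as xr

from . import background as bg
from .occurrences import GriddedPresences
from .sdm import ALGORITHMS, DesignResult, SDMConfig, run_design, select_species

__all__ = ["PlanktonSDMEnsemble", "PlanktonSDMResults"]


class PlanktonSDMEnsemble:
    """Ensemble SDM of many species over shared predictor sets.

    Parameters
    ----------
    presences : GriddedPresences
        Monthly grid-cell presences of every species to model.
    stack : xarray.Dataset
        Predictor stack (present climatology, derived fields included).
    predictor_sets : mapping set_id -> predictor names
    algorithms : sequence of {"GLM", "GAM", "RF", "ANN"}
    background_ratio : int
        Background rows per presence row (target-group stratified draw).
    strata_bins : (n_sst, n_mld)
        Equal-frequency environmental strata for the background draw.
    min_presences : int
        Species below this presence count are not fitted at all.
    """

    def __init__(
        self,
        presences: GriddedPresences,
        stack: xr.Dataset,
        predictor_sets: dict,
        algorithms=ALGORITHMS,
        background_ratio: int = 10,
        strata_bins=(10, 10),
        min_presences: int = 75,
        config: SDMConfig | None = None,
    ):
        self.presences = presences
        self.stack = stack
        self.predictor_sets = dict(predictor_sets)
        self.algorithms = tuple(algorithms)
        self.background_ratio = background_ratio
        self.strata_bins = strata_bins
        self.min_presences = min_presences
        self.config = config or SDMConfig()
        self._strata = None
        self._train_sets = None

    # ------------------------------------------------------------------
    def build_training_sets(self, seed: int = 0) -> dict:
        """Target-group stratified background draw for every species."""
        counts = self.presences.counts()
        eligible = [s for s, n in counts.items() if n >= self.min_presences]
        strata = bg.stratify_environment(
            self.presences, self.stack, *self.strata_bins
        )
        self._strata = strata
        names = sorted({p for ps in self.predictor_sets.values() for p in ps})
        out = {}
        for i, sp in enumerate(sorted(eligible)):
            out[sp] = bg.draw_background(
                sp,
                self.presences,
                self.presences,
                strata,
                self.stack,
                ratio=self.background_ratio,
                seed=seed + i,
                predictor_names=names,
            )
        self._train_sets = out
        return out

    def fit(
        self,
        n_splits: int = 10,
        seed: int = 0,
        climatologies: dict | None = None,
        store_models: bool = True,
    ) -> "PlanktonSDMResults":
        """Run the full factorial design and wrap the outcome."""
        train_sets = self._train_sets or self.build_training_sets(seed=seed)
        scen = dict(climatologies or {})
        scen.setdefault("present", self.stack)
        design = run_design(
            train_sets,
            self.predictor_sets,
            algorithms=self.algorithms,
            n_splits=n_splits,
            seed=seed,
            config=self.config,
            climatologies=scen if climatologies is not None else None,
            store_models=store_models,
        )
        return PlanktonSDMResults(self, design, seed)


@dataclass
class PlanktonSDMResults:
    """Fitted-ensemble results: skill, retention, projections."""

    model: PlanktonSDMEnsemble
    design: DesignResult
    seed: int
    _retained: list = field(default_factory=list, repr=False)

    @property
    def skill(self) -> pd.DataFrame:
        return self.design.skill

    @property
    def hsi(self) -> dict | None:
        return self.design.hsi

    def select_species(self, tss_min: float = 0.30, min_presences: int = 75) -> list:
        retained = select_species(
            self.design.skill, self.model.presences.counts(), tss_min, min_presences
        )
        self._retained = retained
        return retained

    def project(self, stack: xr.Dataset, esm: str | None = None) -> xr.DataArray:
        """Project the stored models onto a predictor stack."""
        if self.design.models is None:
            raise RuntimeError(
                "models were not stored (streamed fit); pass climatologies to fit()"
            )
        from .projection import project_hsi

        return project_hsi(self.design.models, stack, self.model.predictor_sets, esm=esm)

    def summary(self) -> pd.DataFrame:
        """Per-species mean skill, presence counts and retention flags."""
        counts = self.model.presences.counts()
        agg = (
            self.skill.groupby("species_id")[["tss", "auc"]]
            .mean()
            .rename(columns={"tss": "mean_tss", "auc": "mean_auc"})
        )
        agg["n_presences"] = counts.reindex(agg.index)
        retained = set(self._retained or self.select_species())
        agg["retained"] = [s in retained for s in agg.index]
        agg["n_models"] = self.skill.groupby("species_id").size()
        return agg.reset_index()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        s = self.summary()
        lines = [
            "Plankton SDM ensemble results",
            f"  species fitted:   {len(s)}",
            f"  species retained: {int(s['retained'].sum())}",
            f"  skill records:    {len(self.skill)}",
            f"  mean TSS:         {s['mean_tss'].mean():.3f}",
            f"  mean AUC:         {s['mean_auc'].mean():.3f}",
            f"  failures:         {len(self.design.failures)}",
        ]
        return "\n".join(lines)
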