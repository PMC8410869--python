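"""The four-family SDM ensemble: fitting, evaluation and retention.

Four presence/background classifiers of deliberately different flexibility
are fitted per species, predictor set and evaluation split:

* GLM — binomial logit with linear + quadratic terms and bidirectional
  stepwise selection over predictors (AIC criterion).
* GAM — binomial logit on unpenalised B-spline smoothers with basis
  dimension 5 per predictor, no interactions.
* RF  — 750 trees, terminal node size 10, floor(p/3) candidate variables
  per split.
* ANN — single hidden layer; size and weight decay chosen by 5-fold
  cross-validation over a frozen grid, at most 200 iterations.

Row weights (presences 1, background n_presence/n_background) are honoured
by every family.  Skill is measured on held-out 20% splits by the true
skill statistic (max over a 0.01-step probability threshold grid of
sensitivity + specificity - 1) and the AUC.  Species retention requires a
mean TSS strictly above 0.30 and at least 75 presences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "GLMConfig",
    "GAMConfig",
    "RFConfig",
    "ANNConfig",
    "SDMConfig",
    "SDMFitError",
    "FittedSDM",
    "fit_sdm",
    "evaluate_split",
    "tss_score",
    "auc_score",
    "run_design",
    "DesignResult",
    "select_species",
]

ALGORITHMS = ("GLM", "GAM", "RF", "ANN")


class SDMFitError(RuntimeError):
    """A model failed to fit (separation, non-convergence, degenerate data)."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class GLMConfig:
    stepwise: bool = True
    max_steps: int = 50


@dataclass(frozen=True)
class GAMConfig:
    df: int = 5
    degree: int = 3


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 750
    min_node_size: int = 10


@dataclass(frozen=True)
class ANNConfig:
    hidden_sizes: tuple = (2, 4, 6, 8)
    decays: tuple = (0.1, 0.01, 0.001)
    n_folds: int = 5
    max_iter: int = 200


@dataclass(frozen=True)
class SDMConfig:
    glm: GLMConfig = field(default_factory=GLMConfig)
    gam: GAMConfig = field(default_factory=GAMConfig)
    rf: RFConfig = field(default_factory=RFConfig)
    ann: ANNConfig = field(default_factory=ANNConfig)


# ---------------------------------------------------------------------------
# fitted-model wrappers
# ---------------------------------------------------------------------------
class FittedSDM:
    """A fitted probability-of-presence surface over predictor space."""

    algorithm: str = "?"

    def __init__(self, predictors):
        self.predictors = list(predictors)

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            return data[self.predictors].to_numpy(float)
        return np.asarray(data, dtype=float)

    def predict(self, data) -> np.ndarray:
        p = self._predict_impl(self._matrix(data))
        return np.clip(p, 0.0, 1.0)

    def _predict_impl(self, X: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class _Standardizer:
    def __init__(self, X: np.ndarray):
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mu) / self.sd


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-np.clip(z, -35, 35)))


class FittedGLM(FittedSDM):
    algorithm = "GLM"

    def __init__(self, predictors, scaler, params, active):
        super().__init__(predictors)
        self.scaler = scaler
        self.params = params
        self.active = active  # indices of predictors in the final model

    def _predict_impl(self, X):
        Xs = self.scaler(X)[:, self.active]
        design = np.column_stack([np.ones(len(Xs)), Xs, Xs**2])
        return _sigmoid(design @ self.params)


class FittedGAM(FittedSDM):
    algorithm = "GAM"

    def __init__(self, predictors, scaler, basis, params, xmin, xmax):
        super().__init__(predictors)
        self.scaler = scaler
        self.basis = basis
        self.params = params
        self.xmin = xmin
        self.xmax = xmax

    def _predict_impl(self, X):
        Xs = np.clip(self.scaler(X), self.xmin, self.xmax)
        design = np.column_stack([np.ones(len(Xs)), self.basis.transform(Xs)])
        return _sigmoid(design @ self.params)


class FittedRF(FittedSDM):
    algorithm = "RF"

    def __init__(self, predictors, forest):
        super().__init__(predictors)
        self.forest = forest

    def _predict_impl(self, X):
        proba = self.forest.predict_proba(X)
        col = int(np.where(self.forest.classes_ == 1)[0][0])
        return proba[:, col]


class FittedANN(FittedSDM):
    algorithm = "ANN"

    def __init__(self, predictors, scaler, net, params):
        super().__init__(predictors)
        self.scaler = scaler
        self.net = net
        self.hyperparams = params

    def _predict_impl(self, X):
        proba = self.net.predict_proba(self.scaler(X))
        col = int(np.where(self.net.classes_ == 1)[0][0])
        return proba[:, col]


# ---------------------------------------------------------------------------
# per-family fitting
# ---------------------------------------------------------------------------
def _glm_irls(design: np.ndarray, y: np.ndarray, w: np.ndarray,
              maxiter: int = 30, tol: float = 1e-8):
    """Weighted binomial-logit fit by IRLS; returns (params, aic, tvalues).

    A direct iteratively-reweighted-least-squares solver (the textbook GLM
    algorithm) — called thousands of times per species by the stepwise
    search, so it is implemented on raw numpy.  Quasi-separation does not
    raise: the linear predictor is clipped, coefficients stay finite and
    predictions approach 0/1, which is the behaviour wanted when a species'
    niche margin is clean.
    """
    n, k = design.shape
    beta = np.zeros(k)
    pbar = float(np.clip(np.average(y, weights=w), 1e-6, 1 - 1e-6))
    beta[0] = np.log(pbar / (1 - pbar))
    eta = design @ beta
    A = None
    for _ in range(maxiter):
        mu = _sigmoid(eta)
        v = np.clip(mu * (1.0 - mu), 1e-10, None)
        W = w * v
        z = eta + (y - mu) / v
        A = design.T @ (design * W[:, None])
        A[np.diag_indices_from(A)] += 1e-10  # ridge jitter against collinearity
        try:
            beta_new = np.linalg.solve(A, design.T @ (W * z))
        except np.linalg.LinAlgError as exc:
            raise SDMFitError(f"singular IRLS system: {exc}") from exc
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        eta = design @ beta
        if step < tol:
            break
    if not np.all(np.isfinite(beta)):
        raise SDMFitError("GLM produced non-finite coefficients")
    mu = np.clip(_sigmoid(eta), 1e-10, 1 - 1e-10)
    ll = float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))
    aic = -2.0 * ll + 2.0 * k
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(A)
            se = np.sqrt(np.clip(np.diag(cov), 1e-300, None))
            tvalues = beta / se
        except np.linalg.LinAlgError:
            tvalues = np.full(k, np.nan)
    return beta, aic, tvalues


def _glm_design(Xs: np.ndarray, active) -> np.ndarray:
    sub = Xs[:, active]
    return np.column_stack([np.ones(len(Xs)), sub, sub**2])


def _fit_glm(X, y, w, cfg: GLMConfig, predictors) -> FittedGLM:
    scaler = _Standardizer(X)
    Xs = scaler(X)
    p = X.shape[1]
    active = list(range(p))
    params, aic, _ = _glm_irls(_glm_design(Xs, active), y, w)
    if cfg.stepwise and p > 1:
        for _ in range(cfg.max_steps):
            best = (aic, None)
            for j in range(p):
                cand = (
                    [k for k in active if k != j] if j in active else sorted(active + [j])
                )
                if not cand:
                    continue
                try:
                    c_params, c_aic, _ = _glm_irls(_glm_design(Xs, cand), y, w)
                except (SDMFitError, np.linalg.LinAlgError):
                    continue
                if c_aic < best[0] - 1e-9:
                    best = (c_aic, (cand, c_params))
            if best[1] is None:
                break
            aic, (active, params) = best[0], best[1]
    else:
        pass
    return FittedGLM(predictors, scaler, params, active)


def _fit_glm_full(X, y, w, cfg: GLMConfig):
    """Full (no-stepwise) GLM; returns (tvalues, fitted).

    The design layout is [const, linear terms..., quadratic terms...]."""
    scaler = _Standardizer(X)
    Xs = scaler(X)
    design = np.column_stack([np.ones(len(Xs)), Xs, Xs**2])
    params, _, tvalues = _glm_irls(design, y, w)
    fitted = FittedGLM(
        list(range(X.shape[1])), scaler, params, list(range(X.shape[1]))
    )
    return tvalues, fitted


def _fit_gam(X, y, w, cfg: GAMConfig, predictors) -> FittedGAM:
    from statsmodels.gam.smooth_basis import BSplines

    scaler = _Standardizer(X)
    Xs = scaler(X)
    p = X.shape[1]
    try:
        basis = BSplines(
            Xs, df=[cfg.df] * p, degree=[cfg.degree] * p, include_intercept=False
        )
        design = np.column_stack([np.ones(len(Xs)), basis.basis])
        params, _, _ = _glm_irls(design, y, w)
    except (ValueError, np.linalg.LinAlgError) as exc:
        raise SDMFitError(f"GAM basis failure: {exc}") from exc
    return FittedGAM(
        predictors, scaler, basis, params, Xs.min(axis=0), Xs.max(axis=0)
    )


def _fit_rf(X, y, w, cfg: RFConfig, seed: int):
    from sklearn.ensemble import RandomForestClassifier

    p = X.shape[1]
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        min_samples_leaf=cfg.min_node_size,
        max_features=max(1, p // 3),
        random_state=int(seed) % (2**32),
        n_jobs=1,
    )
    forest.fit(X, y.astype(int), sample_weight=w)
    return forest


def _replicate_by_weight(w: np.ndarray) -> np.ndarray:
    """Integer replication counts equivalent to the row weights."""
    rel = w / w.min()
    return np.maximum(np.round(rel).astype(int), 1)


def _ann_search(X, y, w, cfg: ANNConfig, seed: int):
    """5-fold CV over the frozen hidden-size x decay grid; returns best pair."""
    from sklearn.model_selection import StratifiedKFold

    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True,
                          random_state=int(seed) % (2**32))
    folds = list(skf.split(X, y))
    best = (-np.inf, cfg.hidden_sizes[0], cfg.decays[0])
    for h in cfg.hidden_sizes:
        for decay in cfg.decays:
            aucs = []
            for tr, te in folds:
                try:
                    net, scaler = _ann_fit_once(
                        X[tr], y[tr], w[tr], h, decay, cfg.max_iter, seed
                    )
                except SDMFitError:
                    aucs.append(np.nan)
                    continue
                proba = net.predict_proba(scaler(X[te]))
                col = int(np.where(net.classes_ == 1)[0][0])
                aucs.append(auc_score(y[te], proba[:, col], w[te]))
            score = np.nanmean(aucs)
            if score > best[0] + 1e-12:
                best = (score, h, decay)
    return best[1], best[2]


def _ann_fit_once(X, y, w, hidden, decay, max_iter, seed):
    from sklearn.neural_network import MLPClassifier

    scaler = _Standardizer(X)
    rep = _replicate_by_weight(w)
    Xr = np.repeat(scaler(X), rep, axis=0)
    yr = np.repeat(y.astype(int), rep)
    net = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        alpha=decay,
        solver="lbfgs",
        max_iter=max_iter,
        random_state=int(seed) % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net.fit(Xr, yr)
    if len(net.classes_) < 2:
        raise SDMFitError("ANN training data collapsed to one class")
    return net, scaler


def _fit_ann(X, y, w, cfg: ANNConfig, predictors, seed, params=None) -> FittedANN:
    if params is None:
        params = _ann_search(X, y, w, cfg, seed)
    h, decay = params
    net, scaler = _ann_fit_once(X, y, w, h, decay, cfg.max_iter, seed)
    return FittedANN(predictors, scaler, net, params)


def fit_sdm(
    train: pd.DataFrame,
    algorithm: str,
    predictors,
    config: SDMConfig | None = None,
    seed: int = 0,
    ann_params=None,
) -> FittedSDM:
    """Fit one SDM on a training frame with ``response``/``weight`` columns."""
    cfg = config or SDMConfig()
    predictors = list(predictors)
    y = train["response"].to_numpy(float)
    w = train["weight"].to_numpy(float)
    X = train[predictors].to_numpy(float)
    if not (np.any(y == 1) and np.any(y == 0)):
        raise SDMFitError("training set needs both classes")
    if not np.all(np.isfinite(X)):
        raise SDMFitError("non-finite predictor values in training set")
    try:
        if algorithm == "GLM":
            return _fit_glm(X, y, w, cfg.glm, predictors)
        if algorithm == "GAM":
            return _fit_gam(X, y, w, cfg.gam, predictors)
        if algorithm == "RF":
            return FittedRF(predictors, _fit_rf(X, y, w, cfg.rf, seed))
        if algorithm == "ANN":
            return _fit_ann(X, y, w, cfg.ann, predictors, seed, params=ann_params)
    except SDMFitError:
        raise
    except Exception as exc:
        raise SDMFitError(f"{algorithm} fit failed: {exc}") from exc
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ---------------------------------------------------------------------------
# skill metrics
# ---------------------------------------------------------------------------
def tss_score(y, p, w=None, step: float = 0.01) -> float:
    """Max over the 0.01-step threshold grid of sensitivity + specificity - 1."""
    y = np.asarray(y, float)
    p = np.asarray(p, float)
    w = np.ones_like(y) if w is None else np.asarray(w, float)
    pos = y == 1
    wp, wn = w[pos].sum(), w[~pos].sum()
    if wp == 0 or wn == 0:
        return np.nan
    best = -1.0
    for t in np.arange(step, 1.0, step):
        pred = p >= t
        sens = w[pos & pred].sum() / wp
        spec = w[~pos & ~pred].sum() / wn
        best = max(best, sens + spec - 1.0)
    return float(best)


def auc_score(y, p, w=None) -> float:
    from sklearn.metrics import roc_auc_score

    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        return np.nan
    return float(roc_auc_score(y, p, sample_weight=w))


@dataclass
class SkillRecord:
    species_id: str
    algorithm: str
    predictor_set: str
    split_id: int
    tss: float
    auc: float
    flag: str = ""


def evaluate_split(fitted: FittedSDM, test: pd.DataFrame) -> SkillRecord:
    """Held-out TSS and AUC; flagged (NaN skill) on a single-class test set."""
    y = test["response"].to_numpy(float)
    w = test["weight"].to_numpy(float)
    if len(np.unique(y)) < 2:
        return SkillRecord("", fitted.algorithm, "", -1, np.nan, np.nan,
                           flag="single_class_test")
    p = fitted.predict(test)
    return SkillRecord(
        "", fitted.algorithm, "", -1, tss_score(y, p, w), auc_score(y, p, w)
    )


def _stratified_split(y: np.ndarray, test_frac: float, rng) -> tuple:
    """Class-stratified indices (train, test); the test fold keeps presences."""
    test_idx = []
    for cls in (1.0, 0.0):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, int(round(test_frac * len(idx))))
        test_idx.append(rng.permutation(idx)[:n_test])
    test = np.concatenate(test_idx)
    mask = np.ones(len(y), bool)
    mask[test] = False
    return np.flatnonzero(mask), test


# ---------------------------------------------------------------------------
# the full factorial design
# ---------------------------------------------------------------------------
@dataclass
class DesignResult:
    skill: pd.DataFrame
    models: dict | None
    hsi: dict | None
    failures: list
    ann_params: dict

    def mean_skill(self) -> pd.DataFrame:
        return (
            self.skill.groupby("species_id")[["tss", "auc"]].mean().reset_index()
        )


def _prediction_frames(stack: xr.Dataset, names) -> tuple[pd.DataFrame, np.ndarray, tuple]:
    """Flatten a predictor stack to a prediction table over (month, lat, lon)."""
    arrs = {}
    months = stack["month"].values
    nlat, nlon = stack.sizes["lat"], stack.sizes["lon"]
    for n in names:
        a = np.asarray(stack[n], float)
        if a.ndim == 2:
            a = np.broadcast_to(a, (len(months), nlat, nlon))
        arrs[n] = a.reshape(-1)
    df = pd.DataFrame(arrs)
    valid = np.all(np.isfinite(df.to_numpy()), axis=1)
    return df.loc[valid], valid, (len(months), nlat, nlon)


def run_design(
    train_sets: dict,
    predictor_sets: dict,
    algorithms=ALGORITHMS,
    n_splits: int = 10,
    test_frac: float = 0.2,
    seed: int = 0,
    config: SDMConfig | None = None,
    climatologies: dict | None = None,
    store_models: bool = True,
) -> DesignResult:
    """Run the species x algorithm x predictor-set x split factorial.

    For every species, ``len(algorithms) * len(predictor_sets) * n_splits``
    models are trained; each contributes one skill record (minus flagged
    failures).  When ``climatologies`` (scenario name -> predictor stack) is
    given, every model is projected onto each stack immediately after
    fitting and the per-(species, algorithm, set) mean over the splits is
    accumulated into an HSI cube per scenario, so models need not be kept.

    The ANN hidden-size/decay pair is selected once per (species, set) by
    cross-validation on the full training data and reused across splits.
    """
    cfg = config or SDMConfig()
    species_list = sorted(train_sets)
    set_ids = sorted(predictor_sets)
    members = [f"{a}|{s}" for a in algorithms for s in set_ids]

    # Prediction frames, deduplicated: scenarios whose predictor values are
    # bit-identical for a set (e.g. a zero-anomaly future) share one frame,
    # so each model is run once per distinct environment.
    unique_frames = {}
    scen_key = {}
    cubes = None
    if climatologies:
        import hashlib

        for scen, stack in climatologies.items():
            for sid in set_ids:
                frame, valid, shape3 = _prediction_frames(stack, predictor_sets[sid])
                digest = hashlib.md5(
                    np.ascontiguousarray(frame.to_numpy()).tobytes()
                ).hexdigest()
                key = (sid, digest)
                unique_frames.setdefault(key, (frame, valid, shape3))
                scen_key[(scen, sid)] = key
        cubes = {}
        for scen, stack in climatologies.items():
            shape = (len(members), len(species_list), stack.sizes["month"],
                     stack.sizes["lat"], stack.sizes["lon"])
            cubes[scen] = np.full(shape, np.nan)

    records, failures = [], []
    models = {} if store_models else None
    ann_cache = {}

    for i_sp, sp in enumerate(species_list):
        df = train_sets[sp]
        y_all = df["response"].to_numpy(float)
        for i_set, sid in enumerate(set_ids):
            names = list(predictor_sets[sid])
            splits = []
            for run in range(n_splits):
                rng = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(i_sp, i_set, run))
                )
                splits.append(_stratified_split(y_all, test_frac, rng))
            for algo in algorithms:
                ann_params = None
                if algo == "ANN":
                    # hyperparameters are searched once per species (on the
                    # first predictor set) and reused: the sets share most
                    # predictors and the CV optimum is insensitive to the swap
                    if sp not in ann_cache:
                        ann_cache[sp] = _ann_search(
                            df[names].to_numpy(float), y_all,
                            df["weight"].to_numpy(float), cfg.ann,
                            seed + 7 * i_sp,
                        )
                    ann_params = ann_cache[sp]
                member = f"{algo}|{sid}"
                fits_ok = 0
                keys_here = sorted(
                    {scen_key[(scen, sid)] for scen in (climatologies or {})},
                    key=str,
                )
                pred_acc = {key: None for key in keys_here}
                for run, (tr, te) in enumerate(splits):
                    fit_seed = seed + 1000 * i_sp + 100 * i_set + run
                    try:
                        fitted = fit_sdm(
                            df.iloc[tr], algo, names, cfg,
                            seed=fit_seed, ann_params=ann_params,
                        )
                    except SDMFitError as exc:
                        failures.append(
                            {"species_id": sp, "algorithm": algo,
                             "predictor_set": sid, "split_id": run,
                             "error": str(exc)}
                        )
                        continue
                    rec = evaluate_split(fitted, df.iloc[te])
                    rec.species_id, rec.predictor_set, rec.split_id = sp, sid, run
                    records.append(rec)
                    fits_ok += 1
                    if store_models:
                        models.setdefault((sp, algo, sid), []).append(fitted)
                    for key in keys_here:
                        frame, valid, shape3 = unique_frames[key]
                        p = fitted.predict(frame)
                        full = np.full(valid.shape, np.nan)
                        full[valid] = p
                        cube = full.reshape(shape3)
                        if pred_acc[key] is None:
                            pred_acc[key] = cube
                        else:
                            pred_acc[key] += cube
                if cubes is not None and fits_ok > 0:
                    m_idx = members.index(member)
                    for scen in cubes:
                        acc = pred_acc[scen_key[(scen, sid)]]
                        if acc is not None:
                            cubes[scen][m_idx, i_sp] = acc / fits_ok

    skill = pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "algorithm": r.algorithm,
                "predictor_set": r.predictor_set,
                "split_id": r.split_id,
                "tss": r.tss,
                "auc": r.auc,
            }
            for r in records
        ]
    )
    hsi = None
    if cubes is not None:
        hsi = {}
        for scen, arr in cubes.items():
            stack = climatologies[scen]
            hsi[scen] = xr.DataArray(
                arr,
                coords={
                    "member": members,
                    "species": species_list,
                    "month": stack["month"].values,
                    "lat": stack["lat"].values,
                    "lon": stack["lon"].values,
                },
                dims=("member", "species", "month", "lat", "lon"),
                name="hsi",
            )
    return DesignResult(skill, models, hsi, failures, ann_cache)


def select_species(
    skill: pd.DataFrame,
    presence_counts: pd.Series,
    tss_min: float = 0.30,
    min_presences: int = 75,
) -> list:
    """Retain species with mean TSS strictly above ``tss_min`` and at least
    ``min_presences`` grid-cell presences."""
    mean_tss = skill.groupby("species_id")["tss"].mean()
    out = []
    for sp, t in mean_tss.items():
        if np.isnan(t) or t <= tss_min:
            continue
        if presence_counts.get(sp, 0) >= min_presences:
            out.append(sp)
    return sorted(out)
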