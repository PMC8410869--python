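"""SDM fitting, skill metrics against brute-force oracles, retention rules."""

import numpy as np
import pandas as pd
import pytest

from planksdm.sdm import (
    SDMFitError,
    auc_score,
    evaluate_split,
    fit_sdm,
    run_design,
    select_species,
    tss_score,
)
from tests.conftest import make_training_frame

ANN_FIXED = (4, 0.01)  # skip the CV search where hyperparameters are not under test


# ------------------------------------------------------------------ oracles
def oracle_tss(y, p, w, step=0.01):
    best = -1.0
    for t in np.arange(step, 1.0, step):
        tp = fn = tn = fp = 0.0
        for yi, pi, wi in zip(y, p, w):
            if yi == 1:
                if pi >= t:
                    tp += wi
                else:
                    fn += wi
            else:
                if pi >= t:
                    fp += wi
                else:
                    tn += wi
        best = max(best, tp / (tp + fn) + tn / (tn + fp) - 1.0)
    return best


def oracle_auc(y, p, w):
    """Weighted probability that a positive outranks a negative (ties 1/2)."""
    num = den = 0.0
    for i in range(len(y)):
        for j in range(len(y)):
            if y[i] == 1 and y[j] == 0:
                wij = w[i] * w[j]
                den += wij
                if p[i] > p[j]:
                    num += wij
                elif p[i] == p[j]:
                    num += 0.5 * wij
    return num / den


def test_tss_auc_match_bruteforce_oracle():
    rng = np.random.default_rng(0)
    y = (rng.uniform(size=80) < 0.3).astype(float)
    p = rng.uniform(size=80)
    w = rng.uniform(0.1, 1.0, size=80)
    assert tss_score(y, p, w) == pytest.approx(oracle_tss(y, p, w), abs=1e-12)
    assert auc_score(y, p, w) == pytest.approx(oracle_auc(y, p, w), abs=1e-12)


def test_perfect_constant_and_inverted_classifiers():
    y = np.array([1.0, 1.0, 0.0, 0.0])
    perfect = np.array([0.9, 0.8, 0.2, 0.1])
    assert tss_score(y, perfect) == pytest.approx(1.0)
    assert auc_score(y, perfect) == pytest.approx(1.0)
    constant = np.full(4, 0.5)
    assert tss_score(y, constant) == pytest.approx(0.0)
    assert auc_score(y, constant) == pytest.approx(0.5)
    inverted = 1.0 - perfect
    assert auc_score(y, inverted) == pytest.approx(0.0)


# ------------------------------------------------------------------ fitting
@pytest.mark.parametrize("algorithm", ["GLM", "GAM", "RF", "ANN"])
def test_separable_data_fits_near_perfectly(algorithm):
    rng = np.random.default_rng(3)
    n = 100
    x = np.r_[rng.uniform(1.0, 2.0, n), rng.uniform(-2.0, -1.0, n)]
    x2 = rng.normal(size=2 * n)
    df = pd.DataFrame({"x0": x, "x1": x2})
    df["response"] = np.r_[np.ones(n), np.zeros(n)]
    df["weight"] = 1.0
    fitted = fit_sdm(df, algorithm, ["x0", "x1"], seed=0, ann_params=ANN_FIXED)
    p = fitted.predict(df)
    assert p.min() >= 0.0 and p.max() <= 1.0
    assert auc_score(df["response"].to_numpy(), p) >= 0.99


def test_glm_recovers_interior_optimum():
    center, breadth = 1.2, 1.0
    df = make_training_frame(
        n_presence=150, predictors=("x0", "x1"), signal=("x0",),
        center=center, breadth=breadth, seed=5,
    )
    fitted = fit_sdm(df, "GLM", ["x0", "x1"], seed=0)
    grid = np.linspace(-4, 4, 401)
    probe = pd.DataFrame({"x0": grid, "x1": np.zeros_like(grid)})
    opt = grid[np.argmax(fitted.predict(probe))]
    assert abs(opt - center) < breadth / 2


def test_null_response_has_low_skill():
    rng = np.random.default_rng(11)
    tss_vals = []
    for rep in range(5):
        n = 1000
        df = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x0", "x1"])
        df["response"] = (rng.uniform(size=n) < 0.1).astype(float)
        df["weight"] = 1.0
        tr = df.iloc[: int(0.8 * n)]
        te = df.iloc[int(0.8 * n):]
        fitted = fit_sdm(tr, "GLM", ["x0", "x1"], seed=rep)
        rec = evaluate_split(fitted, te)
        tss_vals.append(rec.tss)
    assert abs(np.mean(tss_vals)) < 0.15


def test_single_class_training_raises():
    df = make_training_frame(n_presence=20, seed=1)
    pres_only = df[df["response"] == 1]
    with pytest.raises(SDMFitError):
        fit_sdm(pres_only, "GLM", ["x0", "x1", "x2"], seed=0)


def test_single_class_test_set_flagged():
    df = make_training_frame(n_presence=40, seed=2)
    fitted = fit_sdm(df, "GLM", ["x0", "x1", "x2"], seed=0)
    rec = evaluate_split(fitted, df[df["response"] == 1])
    assert rec.flag == "single_class_test"
    assert np.isnan(rec.tss) and np.isnan(rec.auc)


def test_probabilities_bounded_for_all_algorithms():
    df = make_training_frame(n_presence=60, seed=4)
    probe = pd.DataFrame(
        np.random.default_rng(0).normal(0, 5, size=(500, 3)),
        columns=["x0", "x1", "x2"],
    )
    for algo in ("GLM", "GAM", "RF", "ANN"):
        fitted = fit_sdm(df, algo, ["x0", "x1", "x2"], seed=0, ann_params=ANN_FIXED)
        p = fitted.predict(probe)
        assert np.all((p >= 0.0) & (p <= 1.0))


# ------------------------------------------------------------------ design
@pytest.fixture(scope="module")
def small_design():
    train = {
        f"sp{i}": make_training_frame(n_presence=30, seed=20 + i) for i in range(2)
    }
    sets = {"s1": ("x0", "x1"), "s2": ("x0", "x2")}
    return train, sets


def test_design_record_arithmetic(small_design):
    train, sets = small_design
    res = run_design(train, sets, algorithms=("GLM", "GAM"), n_splits=3, seed=0)
    # records = species x algorithms x sets x splits (no failures here)
    assert len(res.skill) + len(res.failures) == 2 * 2 * 2 * 3
    assert res.skill.groupby(
        ["species_id", "algorithm", "predictor_set"]
    ).size().eq(3).all()


def test_design_is_deterministic(small_design):
    train, sets = small_design
    a = run_design(train, sets, algorithms=("GLM",), n_splits=2, seed=5)
    b = run_design(train, sets, algorithms=("GLM",), n_splits=2, seed=5)
    pd.testing.assert_frame_equal(a.skill, b.skill)


def test_model_store_contains_split_fits(small_design):
    train, sets = small_design
    res = run_design(train, sets, algorithms=("GLM",), n_splits=2, seed=0)
    assert set(res.models) == {
        (sp, "GLM", s) for sp in train for s in sets
    }
    assert all(len(v) == 2 for v in res.models.values())


# ------------------------------------------------------------------ retention
def test_select_species_thresholds():
    skill = pd.DataFrame(
        {
            "species_id": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
            "tss": [0.31] * 4 + [0.30] * 4 + [0.5] * 4,
            "auc": 0.8,
        }
    )
    counts = pd.Series({"a": 80, "b": 80, "c": 74})
    kept = select_species(skill, counts)
    assert kept == ["a"]  # b fails the strict > 0.30 rule; c has 74 presences


def test_select_species_presence_boundary():
    skill = pd.DataFrame({"species_id": ["d"] * 2, "tss": [0.4, 0.4], "auc": 0.8})
    assert select_species(skill, pd.Series({"d": 75})) == ["d"]
    assert select_species(skill, pd.Series({"d": 74})) == []
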