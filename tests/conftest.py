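import warnings

import numpy as np
import pandas as pd
import pytest

from planksdm.grids import GridSpec
from planksdm import synth
from planksdm.predictors import derive_predictors

warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def spec10():
    return GridSpec(cell_size=10.0)


@pytest.fixture(scope="session")
def env(spec10):
    return synth.generate_environment(spec10, seed=1)


@pytest.fixture(scope="session")
def stack(env):
    return derive_predictors(env)


@pytest.fixture(scope="session")
def species20(env):
    return synth.generate_species(20, env, seed=7)


def make_training_frame(
    n_presence=60,
    ratio=10,
    predictors=("x0", "x1", "x2"),
    signal=("x0",),
    center=0.0,
    breadth=1.0,
    seed=0,
):
    """Synthetic presence/background training frame with a known niche.

    Presence probability is a Gaussian bump on the ``signal`` predictors;
    the remaining predictors are pure noise.  Row weights follow the
    presence-1 / background-(n_p/n_b) convention.
    """
    rng = np.random.default_rng(seed)
    n_bg = ratio * n_presence
    rows = []
    n_accept = 0
    while n_accept < n_presence:
        x = rng.normal(0, 2, len(predictors))
        suit = 1.0
        for i, p in enumerate(predictors):
            if p in signal:
                suit *= np.exp(-0.5 * ((x[i] - center) / breadth) ** 2)
        if rng.uniform() < suit:
            rows.append(x)
            n_accept += 1
    X_pres = np.array(rows)
    X_bg = rng.normal(0, 2, (n_bg, len(predictors)))
    X = np.vstack([X_pres, X_bg])
    df = pd.DataFrame(X, columns=list(predictors))
    df["response"] = np.r_[np.ones(n_presence), np.zeros(n_bg)]
    df["weight"] = np.r_[np.ones(n_presence), np.full(n_bg, n_presence / n_bg)]
    return df
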