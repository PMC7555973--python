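import numpy as np
import pandas as pd
import pytest

from persacc.data_model import CriterionMatrix, JudgeRecord, RatingScale, RatingsCube
from persacc.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def default_study():
    """One full-size simulated study shared across read-only tests."""
    return simulate_study(SimulationConfig(seed=20260))


@pytest.fixture
def tiny_cube():
    """2 judges x 3 targets x 3 traits, continuous scale, fully observed."""
    ratings = np.array(
        [
            [[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [4.0, 1.0, 2.0]],
            [[2.0, 2.5, 3.5], [3.0, 3.5, 1.5], [5.0, 1.5, 2.5]],
        ]
    )
    return RatingsCube(
        ["j0", "j1"],
        ["t0", "t1", "t2"],
        ["a", "b", "c"],
        ratings,
        np.zeros((2, 3), dtype=bool),
        RatingScale(1, 5, integer_grid=False),
    )


@pytest.fixture
def tiny_criteria():
    idx = pd.Index(["t0", "t1", "t2"], name="target_id")
    return CriterionMatrix(
        pd.DataFrame(
            {"a": [2.0, 1.0, 5.0], "b": [3.0, 2.0, 1.0], "c": [4.0, 1.0, 3.0]},
            index=idx,
        ),
        pd.Series(["photo"] * 3, index=idx),
        pd.Series(["male", "female", "female"], index=idx),
    )


@pytest.fixture
def tiny_judges():
    return [
        JudgeRecord("j0", "male", 60.0, 15.0, 140.0),
        JudgeRecord("j1", "female", 70.0, 18.0, 160.0),
    ]


def make_random_cube(rng, n_judges, n_targets, n_traits, missing=0.1, levels=None):
    """Small random cube + criteria for oracle-equivalence checks."""
    if levels:
        vals = rng.integers(1, levels + 1, size=(n_judges, n_targets, n_traits)).astype(
            float
        )
    else:
        vals = rng.uniform(1, 5, size=(n_judges, n_targets, n_traits))
    vals[rng.random(vals.shape) < missing] = np.nan
    cube = RatingsCube(
        [f"j{i}" for i in range(n_judges)],
        [f"t{i}" for i in range(n_targets)],
        [f"a{i}" for i in range(n_traits)],
        vals,
        np.zeros((n_judges, n_targets), dtype=bool),
        RatingScale(1, 5, integer_grid=False),
    )
    idx = pd.Index(cube.targets, name="target_id")
    n_mod = min(3, n_targets)
    mods = ["photo", "mute_video", "audio_video"][:n_mod]
    crit = CriterionMatrix(
        pd.DataFrame(
            rng.uniform(1, 5, size=(n_targets, n_traits)),
            index=idx,
            columns=cube.traits,
        ),
        pd.Series([mods[i % n_mod] for i in range(n_targets)], index=idx),
        pd.Series(["male" if i % 2 else "female" for i in range(n_targets)], index=idx),
    )
    return cube, crit
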