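import numpy as np
import pandas as pd
import pytest

import wavefeat as wf
from wavefeat.datasets import VARIABLES


def make_score_table(X, groups, weights=None):
    """Build a ScoreTable directly from a feature matrix for unit tests."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    meta = pd.DataFrame({
        "participant": [f"P{i:03d}" for i in range(n)],
        "trial": np.ones(n, dtype=int),
        "group": list(groups),
        "weight": weights if weights is not None else np.full(n, 1.0 / n),
    })
    cols = [(VARIABLES[j % len(VARIABLES)], j // len(VARIABLES) + 1)
            for j in range(d)]
    scores = pd.DataFrame(
        X, columns=pd.MultiIndex.from_tuples(cols, names=["variable", "pc"]))
    return wf.ScoreTable(meta, scores)


@pytest.fixture(scope="session")
def small_cohort():
    """A small seeded synthetic cohort shared across tests."""
    cfg = wf.CohortConfig(n_symptomatic=10, n_control=5, seed=77)
    return wf.generate_cohort(cfg)


@pytest.fixture(scope="session")
def acceptance_run():
    """Full pipeline run on the default synthetic acceptance cohort."""
    cfg = wf.PipelineConfig(cohort=wf.CohortConfig(), seed=20240908)
    return wf.run_pipeline(cfg)
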