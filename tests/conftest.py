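"""Shared fixtures: small synthetic cohorts generated at test time."""

import numpy as np
import pandas as pd
import pytest

import tempwager as tw
from tempwager import analysis as ana


@pytest.fixture(scope="session")
def inferential_cohort() -> pd.DataFrame:
    """4 hidden-state-inference rats, 6 sessions each (default task)."""
    return pd.concat(
        [
            tw.simulate_rat(
                tw.inferential_agent(), n_sessions=6, rat_id=f"r{r}", seed=10 + r
            )
            for r in range(4)
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def retrospective_cohort() -> pd.DataFrame:
    """4 slow-learning TD rats (α0 = 0.05), 8 sessions each, detrended."""
    df = pd.concat(
        [
            tw.simulate_rat(
                tw.retrospective_agent(alpha0=0.05),
                n_sessions=8,
                rat_id=f"r{r}",
                seed=40 + r,
            )
            for r in range(4)
        ],
        ignore_index=True,
    )
    return ana.detrend_initiation_times(ana.filter_initiation_times(df))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
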