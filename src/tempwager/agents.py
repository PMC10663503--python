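"""Generative agents: synthesize wait and trial-initiation times.

An agent couples a value model (which κ it carries from trial to trial) with
the wait-time and trial-initiation-time models and their log-normal noise.
On each completed trial the agent has a noisy willingness-to-wait drawn
around the model-predicted wait time; it opts out iff the realized reward
delay exceeds that willingness-to-wait (catch trials, whose delay never
elapses, always end in opt-out, censored at the 100-s timeout).  The wait
time is recorded only when the agent opts out.  Every trial, including
violations, carries a trial-initiation time drawn around D/κ with κ taken
*before* the current offer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import CATCH_TIMEOUT, SessionConfig, generate_session
from .timing import (
    TIParams,
    WaitTimeParams,
    predict_trial_initiation,
    predict_wait_time,
    sample_lognormal,
)
from .values import VALUE_MODELS, ValueModelParams, run_value_model


@dataclass
class GenerativeAgent:
    """A value model plus behavioral read-out parameters."""

    value_model: str = "inferential"
    value_params: ValueModelParams = field(default_factory=ValueModelParams)
    wait_params: WaitTimeParams = field(default_factory=WaitTimeParams)
    ti_params: TIParams = field(default_factory=TIParams)

    def __post_init__(self):
        if self.value_model not in VALUE_MODELS:
            raise ValueError(
                f"unknown value model {self.value_model!r}; "
                f"expected one of {VALUE_MODELS}"
            )


def inferential_agent(
    kappa_low: float = 2.0,
    kappa_mixed: float = 4.0,
    kappa_high: float = 8.0,
    D_wt: float = 1.0,
    D_ti: float = 25.0,
    lambda_mix: float = 1.0,
    **kwargs,
) -> GenerativeAgent:
    """Hidden-state-inference agent with block values in μL/s.

    The defaults give seconds-scale wait times under the standard task
    (τ = 2.5 s, catch probability 0.2).
    """
    model = "suboptimal_inferential" if lambda_mix < 1.0 else "inferential"
    return GenerativeAgent(
        value_model=model,
        value_params=ValueModelParams(
            kappa_low=kappa_low,
            kappa_mixed=kappa_mixed,
            kappa_high=kappa_high,
            lambda_mix=lambda_mix,
        ),
        wait_params=WaitTimeParams(D_wt=D_wt, **kwargs),
        ti_params=TIParams(D_ti=D_ti),
    )


def retrospective_agent(
    alpha0: float = 0.1,
    gain_mode: str = "belief_change",
    reward_timescale: float = 10.0,
    kappa_init: float | None = None,
    D_wt: float = 1.0,
    D_ti: float = 25.0,
    **kwargs,
) -> GenerativeAgent:
    """Temporal-difference agent whose κ tracks recent offered rewards.

    ``reward_timescale`` converts offered volumes to a reward rate; the
    default 10 s puts the running average in (0.5, 8) μL/s so generated wait
    times are seconds-scale under the standard task.  ``kappa_init`` defaults
    to the mixed-block mean offer divided by the timescale.
    """
    if kappa_init is None:
        kappa_init = 31.0 / reward_timescale
    return GenerativeAgent(
        value_model="retrospective",
        value_params=ValueModelParams(
            alpha0=alpha0,
            gain_mode=gain_mode,
            kappa_init=kappa_init,
            reward_timescale=reward_timescale,
        ),
        wait_params=WaitTimeParams(D_wt=D_wt, **kwargs),
        ti_params=TIParams(D_ti=D_ti),
    )


def generate_behavior(
    trials: pd.DataFrame,
    agent: GenerativeAgent,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fill the behavioral columns of a task trial table (one session).

    Returns a copy with ``opted_out``, ``rewarded``, ``wait_time`` and
    ``trial_initiation_time`` populated.  ``wait_time`` is present iff the
    agent opted out; catch-trial waits are censored at the 100-s timeout.
    """
    df = trials.copy()
    trace = run_value_model(df, agent.value_model, agent.value_params)

    offers = df["reward_offer"].to_numpy(dtype=float)
    is_catch = df["is_catch"].to_numpy(dtype=bool)
    is_viol = df["is_violation"].to_numpy(dtype=bool)
    delays = df["reward_delay"].to_numpy(dtype=float)

    wt_pred = predict_wait_time(offers, trace.kappa, agent.wait_params)
    ti_pred = predict_trial_initiation(trace.kappa_pre, agent.ti_params)

    # one noise draw per trial for each read-out, in trial order
    willingness = sample_lognormal(
        wt_pred, agent.wait_params.noise_var_wt, rng
    )
    ti_obs = sample_lognormal(ti_pred, agent.ti_params.noise_var_ti, rng)

    opted_out = ~is_viol & (is_catch | (delays > willingness))
    rewarded = ~is_viol & ~is_catch & (delays <= willingness)
    wait = np.where(opted_out, np.minimum(willingness, np.where(is_catch, CATCH_TIMEOUT, np.inf)), np.nan)

    df["opted_out"] = opted_out
    df["rewarded"] = rewarded
    df["wait_time"] = wait
    df["trial_initiation_time"] = ti_obs
    return df


def simulate_rat(
    agent: GenerativeAgent,
    config: SessionConfig | None = None,
    n_sessions: int = 1,
    rat_id: str = "rat0",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a rat: task structure + behavior for ``n_sessions`` sessions.

    One RNG stream per session, derived from ``seed`` via SeedSequence, so
    sessions are reproducible independently of how many are generated.
    """
    if config is None:
        config = SessionConfig()
    frames = []
    for s, child in enumerate(np.random.SeedSequence(seed).spawn(n_sessions)):
        rng = np.random.default_rng(child)
        task = generate_session(config, rng, rat_id=rat_id, session_id=f"s{s:03d}")
        frames.append(generate_behavior(task, agent, rng))
    return pd.concat(frames, ignore_index=True)


def simulate_trials(
    agent: GenerativeAgent,
    n_trials: int,
    config: SessionConfig | None = None,
    rat_id: str = "rat0",
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate whole sessions until at least ``n_trials`` trials exist."""
    if config is None:
        config = SessionConfig()
    frames = []
    total = 0
    ss = np.random.SeedSequence(seed)
    s = 0
    while total < n_trials:
        rng = np.random.default_rng(ss.spawn(1)[0])
        task = generate_session(config, rng, rat_id=rat_id, session_id=f"s{s:03d}")
        df = generate_behavior(task, agent, rng)
        frames.append(df)
        total += len(df)
        s += 1
    return pd.concat(frames, ignore_index=True)
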