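"""Task generator: block grammar, completed-trial counts, offers, delays."""

import numpy as np
import pytest

import tempwager as tw
from tempwager.inference import BLOCK_REWARDS
from tempwager.task import FEMALE_REWARDS, SessionConfig, generate_session


class _Coin:
    """Stub RNG whose first draw fixes which adaptation block comes first."""

    def __init__(self, first):
        self.u = 0.25 if first == "high" else 0.75

    def random(self):
        return self.u


def test_block_sequence_examples():
    assert tw.generate_block_sequence(1, _Coin("high")) == ["mixed"]
    assert tw.generate_block_sequence(4, _Coin("high")) == [
        "mixed", "high", "mixed", "low",
    ]
    assert tw.generate_block_sequence(5, _Coin("low")) == [
        "mixed", "low", "mixed", "high", "mixed",
    ]
    with pytest.raises(ValueError):
        tw.generate_block_sequence(0, _Coin("high"))


def test_block_sequence_grammar_over_many_seeds():
    for seed in range(1000):
        seq = tw.generate_block_sequence(9, np.random.default_rng(seed))
        assert seq[0] == "mixed"
        assert all(seq[i] == "mixed" for i in range(0, 9, 2))
        adapt = seq[1::2]
        assert set(adapt) <= {"high", "low"}
        assert all(a != b for a, b in zip(adapt, adapt[1:]))  # strict alternation


def test_reward_delay_moments(rng):
    d = tw.draw_reward_delay(2.5, rng, size=100_000)
    assert np.all(d >= 0)
    assert d.mean() == pytest.approx(2.5, rel=0.02)
    assert d.var(ddof=1) == pytest.approx(6.25, rel=0.05)
    with pytest.raises(ValueError):
        tw.draw_reward_delay(0.0, rng)


@pytest.mark.parametrize("violation_prob", [0.0, 0.2, 0.45])
def test_completed_trials_per_block_exact(violation_prob):
    for seed in range(5):
        cfg = SessionConfig(n_blocks=5, violation_prob=violation_prob, rng_seed=seed)
        df = generate_session(cfg)
        # block identity changes exactly every 40 completed (non-violation) trials
        completed_per_block = (~df["is_violation"]).groupby(
            (df["block"] != df["block"].shift()).cumsum()
        ).sum()
        assert (completed_per_block == 40).all()
        if violation_prob == 0.0:
            assert df.groupby((df["block"] != df["block"].shift()).cumsum()).size().eq(40).all()


def test_offers_respect_block_membership():
    df = generate_session(SessionConfig(n_blocks=9, rng_seed=7))
    for block, g in df.groupby("block"):
        assert set(g["reward_offer"]) <= set(BLOCK_REWARDS[block])


def test_violation_repeats_offer():
    df = generate_session(SessionConfig(n_blocks=9, violation_prob=0.3, rng_seed=3))
    offers = df["reward_offer"].to_numpy()
    viol = df["is_violation"].to_numpy()
    same_block = df["block"].to_numpy()[:-1] == df["block"].to_numpy()[1:]
    for i in np.flatnonzero(viol[:-1] & same_block):
        assert offers[i + 1] == offers[i]


def test_catch_fraction_matches_config():
    frames = [
        generate_session(SessionConfig(catch_prob=0.15, n_blocks=9, rng_seed=s))
        for s in range(300)
    ]
    import pandas as pd

    df = pd.concat(frames)
    completed = df.loc[~df["is_violation"]]
    assert len(completed) >= 100_000
    assert completed["is_catch"].mean() == pytest.approx(0.15, abs=0.01)
    # violations never carry the catch flag
    assert not df.loc[df["is_violation"], "is_catch"].any()


def test_female_scaling_relabels_to_male_volumes():
    df = generate_session(SessionConfig(female_scaling=True, rng_seed=1))
    assert set(df["reward_offer"]) <= {5.0, 10.0, 20.0, 40.0, 80.0}
    assert not set(df["reward_offer"]) & set(FEMALE_REWARDS)


def test_config_validation():
    with pytest.raises(ValueError):
        SessionConfig(catch_prob=1.5)
    with pytest.raises(ValueError):
        SessionConfig(mean_delay=-1.0)
    with pytest.raises(ValueError):
        SessionConfig(reward_set=(5, 10, 20, 40))
    with pytest.raises(ValueError):
        SessionConfig(reward_set=(5, 10, 20, 40, 30))


def test_generate_behavior_noise_free_limit():
    cfg = SessionConfig(n_blocks=3, violation_prob=0.0, rng_seed=5)
    df = generate_session(cfg)
    agent = tw.GenerativeAgent(
        value_model="inferential",
        wait_params=tw.WaitTimeParams(noise_var_wt=1e-12),
        ti_params=tw.TIParams(noise_var_ti=1e-12),
    )
    out = tw.generate_behavior(df, agent, np.random.default_rng(0))
    from tempwager.values import run_value_model
    from tempwager.timing import predict_wait_time, predict_trial_initiation

    trace = run_value_model(df, "inferential", agent.value_params)
    wt = predict_wait_time(
        out["reward_offer"].to_numpy(float), trace.kappa, agent.wait_params
    )
    ti = predict_trial_initiation(trace.kappa_pre, agent.ti_params)
    catch = out["is_catch"].to_numpy(bool)
    assert np.allclose(out.loc[catch, "wait_time"], wt[catch], rtol=5e-3)
    assert np.allclose(out["trial_initiation_time"], ti, rtol=5e-3)


def test_generate_behavior_invariants(inferential_cohort):
    df = inferential_cohort
    # wait time present iff opted out
    assert df["wait_time"].notna().equals(df["opted_out"])
    # rewarded implies neither opted out nor violation
    r = df.loc[df["rewarded"]]
    assert not r["opted_out"].any() and not r["is_violation"].any()
    # catch trials always end in opt-out, censored at the timeout
    catch = df.loc[df["is_catch"]]
    assert catch["opted_out"].all()
    assert catch["wait_time"].max() <= 100.0
    assert (df["trial_initiation_time"] > 0).all()


def test_contextual_wait_pattern_inferential(inferential_cohort):
    """20-μL waits are longer in low than high blocks for an inference agent."""
    df = inferential_cohort
    sel = df[(df["reward_offer"] == 20.0) & df["is_catch"] & df["wait_time"].notna()]
    lo = sel.loc[sel["block"] == "low", "wait_time"].mean()
    hi = sel.loc[sel["block"] == "high", "wait_time"].mean()
    assert lo > hi
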