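"""Behavioral analyses: filters, ratios, dynamics, kernels, misinference."""

import numpy as np
import pandas as pd
import pytest

import tempwager as tw
from tempwager import analysis as ana
from tempwager.fitting import EmptyDataError


def _catch_frame(waits, rat="r0", session="s0", offer=20.0):
    n = len(waits)
    return pd.DataFrame(
        {
            "rat_id": rat,
            "session_id": session,
            "trial_index": np.arange(1, n + 1),
            "block": "mixed",
            "trial_in_block": np.arange(1, n + 1),
            "reward_offer": offer,
            "is_catch": True,
            "is_violation": False,
            "reward_delay": 2.5,
            "opted_out": True,
            "rewarded": False,
            "wait_time": waits,
            "trial_initiation_time": 1.0,
        }
    )


# ----------------------------------------------------------------- filters

def test_filter_wait_times_worked_example():
    df = _catch_frame([1.0, 2.0, 3.0, 100.0])
    out = ana.filter_wait_times(df)
    # mean 26.5, SD 48.22 -> cutoff 74.72 removes only the 100
    assert out["wait_time"].notna().sum() == 3
    assert np.isnan(out["wait_time"].iloc[3])


def test_filter_wait_times_all_equal_untouched():
    out = ana.filter_wait_times(_catch_frame([2.0] * 10))
    assert out["wait_time"].notna().all()


def test_filter_wait_times_not_idempotent():
    df = _catch_frame([1.0, 1.0, 1.0, 2.0, 10.0])
    once = ana.filter_wait_times(df)
    twice = ana.filter_wait_times(once)
    assert once["wait_time"].notna().sum() == 4
    assert twice["wait_time"].notna().sum() == 3  # recomputed cutoff bites again


def test_filter_initiation_times_percentile():
    n = 1000
    df = _catch_frame(np.ones(n))
    df["trial_initiation_time"] = np.random.default_rng(0).uniform(0, 1, n)
    out = ana.filter_initiation_times(df)
    assert out["trial_initiation_time"].isna().sum() == 10
    same = _catch_frame(np.ones(20))
    assert ana.filter_initiation_times(same)["trial_initiation_time"].notna().all()


def test_filter_initiation_times_removes_max_heavy_tail():
    for seed in range(10):
        df = _catch_frame(np.ones(500))
        ti = np.random.default_rng(seed).pareto(1.1, 500) + 0.1
        df["trial_initiation_time"] = ti
        out = ana.filter_initiation_times(df)
        assert np.isnan(out["trial_initiation_time"].iloc[np.argmax(ti)])


def test_detrend_removes_exact_linear_trend():
    n = 101
    df = _catch_frame(np.ones(n))
    tn = np.arange(1, n + 1, dtype=float)
    z = (tn - tn.mean()) / tn.std()
    df["trial_initiation_time"] = 2.0 + 0.5 * z
    out = ana.detrend_initiation_times(df)
    assert np.allclose(out["ti_detrended"], 2.0, atol=1e-10)


def test_detrend_preserves_block_structure():
    """A block effect survives detrending; a linear drift does not."""
    rng = np.random.default_rng(0)
    n = 400
    df = _catch_frame(np.ones(n))
    df["block"] = np.where(np.arange(n) % 80 < 40, "low", "high")
    block_effect = np.where(df["block"] == "low", 2.0, -2.0)
    drift = 0.02 * np.arange(n)
    df["trial_initiation_time"] = 10.0 + block_effect + drift + rng.normal(0, 0.1, n)
    out = ana.detrend_initiation_times(df)
    resid = out["ti_detrended"]
    lo = resid[df["block"] == "low"].mean()
    hi = resid[df["block"] == "high"].mean()
    assert lo - hi > 3.0
    slope = np.polyfit(np.arange(n), resid, 1)[0]
    assert abs(slope) < 5e-3


# ------------------------------------------------------- session inclusion

def _slope_session(rat, sid, slope, noise, n=60, seed=0):
    rng = np.random.default_rng(seed)
    offers = rng.choice([5.0, 10.0, 20.0, 40.0, 80.0], n)
    df = _catch_frame(np.ones(n), rat=rat, session=sid)
    df["reward_offer"] = offers
    df["wait_time"] = 5.0 + slope * offers + rng.normal(0, noise, n)
    df["wait_time"] = df["wait_time"].clip(lower=0.1)
    return df


def test_session_inclusion_rule():
    sessions = [
        _slope_session("r0", "s0", 0.20, 0.5, seed=1),   # significantly +
        _slope_session("r0", "s1", 0.02, 4.0, seed=2),   # + but not significant
        _slope_session("r0", "s2", 0.20, 0.5, seed=3),   # significantly +
        _slope_session("r0", "s3", -0.20, 0.5, seed=4),  # negative
    ]
    df = pd.concat(sessions, ignore_index=True)
    inc = ana.session_inclusion(df).set_index("session_id")
    assert inc.loc["s0", "include"]  # sig+, next slope positive
    assert not inc.loc["s1", "include"]  # not itself significant
    assert not inc.loc["s2", "include"]  # next slope negative
    assert not inc.loc["s3", "include"]  # negative (and last)


def test_session_inclusion_all_negative_none_included():
    df = pd.concat(
        [_slope_session("r0", f"s{i}", -0.2, 0.5, seed=i) for i in range(3)],
        ignore_index=True,
    )
    assert not ana.session_inclusion(df)["include"].any()


def test_session_inclusion_single_session_excluded():
    df = _slope_session("r0", "s0", 0.2, 0.5)
    assert not ana.session_inclusion(df)["include"].any()


# ------------------------------------------------------- block sensitivity

def test_block_sensitivity_identical_behavior_ratio_one():
    df = pd.concat(
        [
            _catch_frame([4.0] * 30, session="s0"),
            _catch_frame([4.0] * 30, session="s1"),
        ],
        ignore_index=True,
    )
    df.loc[df["session_id"] == "s0", "block"] = "high"
    df.loc[df["session_id"] == "s1", "block"] = "low"
    out = ana.block_sensitivity(df, "wait")
    assert out["ratio"].iloc[0] == pytest.approx(1.0)


def test_block_sensitivity_directions(inferential_cohort, retrospective_cohort):
    wait = ana.block_sensitivity(inferential_cohort, "wait")
    assert (wait["ratio"] < 1.0).all()  # less patient when environment is rich
    ti = ana.block_sensitivity(retrospective_cohort, "initiation")
    assert (ti["ratio"] < 1.0).all()  # faster initiation in high blocks


def test_block_sensitivity_missing_block_errors():
    df = _catch_frame([1.0] * 10)  # mixed only
    with pytest.raises(EmptyDataError):
        ana.block_sensitivity(df, "wait")


# ----------------------------------------------------- transition dynamics

def test_transition_curve_null_when_block_independent(rng):
    frames = []
    for r in range(3):
        df = tw.generate_session(tw.SessionConfig(n_blocks=9, rng_seed=r), rat_id=f"r{r}")
        df["wait_time"] = np.where(df["is_catch"], rng.normal(5, 1, len(df)), np.nan)
        df["trial_initiation_time"] = rng.normal(3, 0.5, len(df))
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    c = ana.transition_dynamics(df, "high->mixed", "wait")
    assert np.nanmean(np.abs(c.values)) < 0.35  # pure noise, smoothed


def test_transition_requires_existing_transitions():
    df = _catch_frame([1.0] * 50)
    with pytest.raises(EmptyDataError):
        ana.transition_dynamics(df, "high->mixed", "wait")
    with pytest.raises(ValueError):
        ana.transition_dynamics(df, "high->low", "wait")


def test_overshoot_trivial_cases():
    offs = np.arange(-5, 41)
    mono = np.where(offs < 0, 0.0, np.minimum(offs, 20) / 20.0)  # peak at 20
    c = ana.TransitionCurve("high->mixed", offs, mono, mono[None, :], ["r0"])
    assert ana.overshoot(c) == pytest.approx(0.0)
    flat = ana.TransitionCurve("high->mixed", offs, np.zeros(offs.size), None, ["r0"])
    assert ana.overshoot(flat) == 0.0
    short = ana.TransitionCurve("high->mixed", np.arange(-5, 15), np.zeros(20), None, ["r0"])
    with pytest.raises(ValueError):
        ana.overshoot(short)


# ----------------------------------------------------------- logistic fits

def test_logistic_recovery_and_shape():
    rng = np.random.default_rng(2)
    x = np.arange(-20, 41, dtype=float)
    true = ana.LogisticParams(A=0.0, D_log=1.0, C_inv=1.0, x0=0.0)
    y = true(x) + rng.normal(0, 0.02, x.size)
    fit = ana.fit_logistic(x, y)
    assert fit.A == pytest.approx(0.0, abs=0.1)
    assert fit.D_log == pytest.approx(1.0, rel=0.1)
    assert fit.C_inv == pytest.approx(1.0, rel=0.35)
    assert fit.x0 == pytest.approx(0.0, abs=1.0)
    # midpoint and asymptote identities
    assert fit(fit.x0) == pytest.approx((fit.A + fit.D_log) / 2, rel=1e-6)
    assert fit(1e6) == pytest.approx(fit.D_log, abs=1e-6)
    assert fit.A <= fit.D_log


def test_shuffle_test_detects_planted_difference(rng):
    x = np.arange(-10, 31, dtype=float)
    steep = ana.LogisticParams(A=0.0, D_log=1.0, C_inv=2.0, x0=5.0)
    shallow = ana.LogisticParams(A=0.0, D_log=1.0, C_inv=0.15, x0=5.0)
    a = np.vstack([steep(x) + rng.normal(0, 0.03, x.size) for _ in range(8)])
    b = np.vstack([shallow(x) + rng.normal(0, 0.03, x.size) for _ in range(8)])
    out = ana.shuffle_test_logistic(a, b, x=x, n_shuffles=100, rng=rng).set_index("parameter")
    assert out.loc["C_inv", "p_upper"] < 0.05
    with pytest.raises(ValueError):
        ana.shuffle_test_logistic(a[:1], b, x=x, rng=rng)


# -------------------------------------------------------- history effects

def test_previous_offer_sensitivity_directions(
    inferential_cohort, retrospective_cohort
):
    """TD agents are history sensitive; a flat-noise control is not."""
    retro = ana.previous_offer_sensitivity(retrospective_cohort, "initiation")
    assert retro["delta"].mean() > 0.2  # slower after small offers
    # block-independent noise control
    rng = np.random.default_rng(3)
    frames = []
    for r in range(3):
        for s in range(12):
            df = tw.generate_session(
                tw.SessionConfig(n_blocks=9, rng_seed=50 + 20 * r + s),
                rat_id=f"r{r}", session_id=f"s{s:02d}",
            )
            df["wait_time"] = np.where(df["is_catch"], rng.normal(5, 1, len(df)), np.nan)
            df["trial_initiation_time"] = rng.normal(3, 0.5, len(df))
            frames.append(df)
    null = ana.previous_offer_sensitivity(pd.concat(frames, ignore_index=True), "wait")
    assert abs(null["delta"].mean()) < 0.3
    # the history-driven TD effect dwarfs the inference agent's residual one
    inf_wait = ana.previous_offer_sensitivity(inferential_cohort, "wait")
    retro_ti = retro["delta"].mean()
    assert retro_ti > inf_wait["delta"].mean() - 0.2


def test_history_regression_wait_current_offer_dominates(inferential_cohort):
    one = inferential_cohort[inferential_cohort["rat_id"] == "r0"]
    res = ana.history_regression(one, "wait")
    assert res.current_offer_coef > 0.3
    assert res.tau_hist == 0.0  # previous-offer kernel zeroed
    assert np.all(res.coefficients[res.first_nonsig:] == 0.0) if res.first_nonsig else True


def test_history_regression_pure_noise_all_zeroed(rng):
    frames = []
    for s in range(6):
        df = tw.generate_session(tw.SessionConfig(n_blocks=9, rng_seed=60 + s),
                                 rat_id="r0", session_id=f"s{s}")
        df["wait_time"] = np.where(df["is_catch"], rng.lognormal(1.5, 0.5, len(df)), np.nan)
        df["trial_initiation_time"] = rng.lognormal(1.0, 0.5, len(df))
        frames.append(df)
    df = pd.concat(frames, ignore_index=True)
    res = ana.history_regression(df, "initiation")
    assert np.allclose(res.coefficients, 0.0)
    assert res.tau_hist == 0.0


def test_history_regression_insufficient_rows():
    one = _catch_frame([1.0] * 30)
    with pytest.raises(EmptyDataError):
        ana.history_regression(one, "wait")


def test_fit_exponential_decay_cases():
    x = np.arange(9, dtype=float)
    D, tau = ana.fit_exponential_decay(0.5 * np.exp(-x / 2.0))
    assert D == pytest.approx(0.5, rel=1e-4)
    assert tau == pytest.approx(2.0, rel=1e-4)
    assert ana.fit_exponential_decay(np.zeros(9)) == (0.0, 0.0)
    D1, tau1 = ana.fit_exponential_decay(np.array([0.6] + [0.0] * 8))
    assert D1 == pytest.approx(0.6, rel=0.05)
    assert tau1 < 0.5


# ------------------------------------------------------- learning dynamics

def test_learning_dynamics_flat_agent_flat_coefficients(inferential_cohort):
    ld = ana.learning_dynamics(inferential_cohort)
    coefs = ld["coefficients"]
    wb = coefs[coefs["coefficient"] == "wait_block"]
    per_rat_sd = wb.groupby("rat_id")["smoothed"].std()
    per_rat_mean = wb.groupby("rat_id")["smoothed"].mean().abs()
    assert (per_rat_sd < per_rat_mean.clip(lower=0.05) * 2.0).all()
    assert len(ld["pair_ratios"]) == 4 * 3  # 4 rats, 6 sessions -> 3 pairs


def test_learning_dynamics_planted_trend():
    """Ramping the block-value separation across sessions grows the block
    coefficient magnitude."""
    frames = []
    for s, d in enumerate(np.linspace(0.0, 2.5, 8)):
        agent = tw.inferential_agent(kappa_low=4.0 - d, kappa_mixed=4.0, kappa_high=4.0 + d)
        df = tw.simulate_rat(agent, tw.SessionConfig(n_blocks=9), n_sessions=1,
                             rat_id="r0", seed=70 + s)
        df["session_id"] = f"s{s:03d}"
        frames.append(df)
    ld = ana.learning_dynamics(pd.concat(frames, ignore_index=True))
    wb = ld["coefficients"]
    wb = wb[wb["coefficient"] == "wait_block"].set_index("session_id")["smoothed"].abs()
    assert wb.iloc[-1] > wb.iloc[0]


def test_moving_median_outlier_rule():
    x = np.array([1.0, 1.1, 0.9, 1.0, 10.0, 1.1, 0.9, 1.0, 1.05])
    flags = ana._moving_median_outliers(x, window=5, thresh=3.0)
    assert flags[4]
    assert flags.sum() == 1


# ------------------------------------------------------------ misinference

def test_misinference_flags_after_high_block():
    offers = [80.0] * 40 + [40.0, 80.0, 20.0, 40.0] + [5.0] + [20.0] * 5
    df = _catch_frame(np.ones(len(offers)))
    df["reward_offer"] = offers
    df["block"] = ["high"] * 40 + ["mixed"] * 10
    trace = tw.run_value_model(df, "inferential", tw.ValueModelParams())
    flags = ana.misinference_trials(df, trace)
    # early mixed trials with big offers still look like a high block
    assert (flags.iloc[40:44] == "misinferred-high").all()
    # a 5-μL offer annihilates p_high: no misinferred-high right afterwards
    assert flags.iloc[44] != "misinferred-high"
    assert flags.iloc[45] != "misinferred-high"
    assert (flags.iloc[:40] == "none").all()  # only mixed trials are flagged


def test_misinference_accepts_fitted_results(inferential_cohort):
    one = inferential_cohort[inferential_cohort["rat_id"] == "r0"]
    res = tw.WaitTimeModel(one, "inferential", catch_prob=0.2).fit(
        n_starts=3, seed=0, refine=False
    )
    flags = ana.misinference_trials(one, res)
    assert len(flags) == len(one)
    assert set(flags.unique()) <= {"none", "misinferred-low", "misinferred-high"}
    # flags appear only inside mixed blocks
    assert (flags[one["block"] != "mixed"] == "none").all()


def test_analyses_invariant_to_rat_relabeling(inferential_cohort):
    """Per-rat scoping: relabeling rats and reordering blocks of rows does
    not change per-rat statistics."""
    df = inferential_cohort
    relabeled = df.copy()
    relabeled["rat_id"] = relabeled["rat_id"].map(
        {"r0": "zz", "r1": "aa", "r2": "mm", "r3": "bb"}
    )
    # concatenate rats in a different order, keeping within-rat row order
    reordered = pd.concat(
        [relabeled[relabeled["rat_id"] == r] for r in ("mm", "zz", "bb", "aa")],
        ignore_index=True,
    )
    a = ana.block_sensitivity(df, "wait").set_index("rat_id")["ratio"]
    b = ana.block_sensitivity(reordered, "wait").set_index("rat_id")["ratio"]
    mapping = {"r0": "zz", "r1": "aa", "r2": "mm", "r3": "bb"}
    for old, new in mapping.items():
        assert a[old] == pytest.approx(b[new], rel=1e-12)


def test_misinference_none_when_evidence_mixed():
    # strictly alternating extremes are only consistent with a mixed block
    offers = np.array([5.0, 80.0] * 30)
    df = _catch_frame(np.ones(60))
    df["reward_offer"] = offers
    trace = tw.run_value_model(df, "inferential", tw.ValueModelParams())
    flags = ana.misinference_trials(df, trace)
    assert (flags.iloc[5:] == "none").all()
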