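"""Behavioral statistics: filters, ratios, dynamics, history kernels.

These are the trial-table analyses used to characterize wait-time and
trial-initiation-time behavior:

- inclusion / outlier filters (session slope criterion, pooled 1-SD wait
  filter, 99th-percentile initiation filter, within-session detrending)
- block-sensitivity ratios (high/low) with rank-sum tests
- block-transition dynamics (Δ z-scored curves), 4-parameter logistic fits
  and label-shuffle significance tests
- previous-offer sensitivity and trial-history regressions with
  exponential-decay kernel fits
- across-session learning dynamics and the post-transition overshoot metric
- misinference flagging from a fitted hidden-state model

Filter order, when several are combined: the session-local 2-SD trim is used
only inside the inclusion criterion; analyses then apply the pooled 1-SD
wait filter, the 99th-percentile initiation filter, and per-session
detrending, in that order.  All per-rat quantities scope by ``rat_id``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
from scipy.optimize import least_squares
import statsmodels.api as sm

from .fitting import EmptyDataError, FittingError
from .values import ValueTrace

TRANSITIONS = ("low->mixed", "high->mixed", "mixed->low", "mixed->high")


# ----------------------------------------------------------------------
# filtering and inclusion
# ----------------------------------------------------------------------

def filter_wait_times(trials: pd.DataFrame, sd_mult: float = 1.0) -> pd.DataFrame:
    """Remove catch-trial wait times above the pooled mean + ``sd_mult``·SD.

    Pooling is per rat across its sessions.  Outlying waits are set to NaN
    (rows are kept so initiation-time analyses are unaffected).  Reapplying
    the filter recomputes the cutoff on the filtered set, so it is not
    idempotent by construction.
    """
    out = trials.copy()
    scored = out["is_catch"].astype(bool) & out["wait_time"].notna()
    if not scored.any():
        raise EmptyDataError("no catch-trial wait times to filter")
    for _, idx in out.loc[scored].groupby("rat_id", sort=False).groups.items():
        w = out.loc[idx, "wait_time"]
        cut = w.mean() + sd_mult * w.std(ddof=1)
        if np.isnan(cut):  # single observation: SD undefined, keep it
            continue
        out.loc[idx[w > cut], "wait_time"] = np.nan
    return out


def _session_slope(wait: np.ndarray, offers: np.ndarray) -> tuple[float, float]:
    """OLS slope of wait on offer and its one-sided (positive) p-value."""
    if wait.size < 3 or np.unique(offers).size < 2:
        return np.nan, 1.0
    X = sm.add_constant(offers)
    fit = sm.OLS(wait, X).fit()
    slope = fit.params[1]
    p_two = fit.pvalues[1]
    p_one = p_two / 2.0 if slope > 0 else 1.0 - p_two / 2.0
    return float(slope), float(p_one)


def session_inclusion(trials: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Which sessions show reliable wait-time sensitivity to the offer.

    Per session: trim catch waits above the session mean + 2 SD (the trim is
    local to this criterion), regress wait on offered reward, and call the
    session significantly positive at one-sided p < ``alpha``.  A session is
    included iff it is significantly positive AND the next session's slope is
    positive (any significance).  Rats with fewer than two sessions have all
    sessions excluded.
    """
    rows = []
    for rat, g in trials.groupby("rat_id", sort=False):
        sess = []
        for sid, s in g.groupby("session_id", sort=False):
            catch = s.loc[s["is_catch"].astype(bool) & s["wait_time"].notna()]
            w = catch["wait_time"].to_numpy(dtype=float)
            r = catch["reward_offer"].to_numpy(dtype=float)
            if w.size:
                cut = w.mean() + 2.0 * w.std(ddof=1)
                keep = w <= cut if w.size > 1 else np.ones(w.size, bool)
                w, r = w[keep], r[keep]
            slope, p = _session_slope(w, r)
            sess.append({"rat_id": rat, "session_id": sid, "slope": slope, "p_one_sided": p})
        for i, row in enumerate(sess):
            sig_pos = (row["slope"] > 0) and (row["p_one_sided"] < alpha)
            has_next = i + 1 < len(sess)
            next_pos = has_next and sess[i + 1]["slope"] > 0
            row["include"] = bool(len(sess) >= 2 and sig_pos and next_pos)
            rows.append(row)
    return pd.DataFrame(rows)


def filter_initiation_times(trials: pd.DataFrame, percentile: float = 99.0) -> pd.DataFrame:
    """Drop initiation times above the rat's pooled percentile (default 99th)."""
    out = trials.copy()
    has_ti = out["trial_initiation_time"].notna()
    for rat, idx in out.loc[has_ti].groupby("rat_id", sort=False).groups.items():
        ti = out.loc[idx, "trial_initiation_time"]
        cut = np.percentile(ti, percentile)
        out.loc[idx[ti > cut], "trial_initiation_time"] = np.nan
    return out


def detrend_initiation_times(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove within-session linear drift (satiety) from initiation times.

    Per session, regress TI on the z-scored trial number and keep residuals
    plus the session mean, in a new ``ti_detrended`` column.  Sessions with
    fewer than 3 usable trials pass through with a warning.
    """
    out = trials.copy()
    out["ti_detrended"] = out["trial_initiation_time"]
    for (rat, sid), g in out.groupby(["rat_id", "session_id"], sort=False):
        ok = g["trial_initiation_time"].notna()
        if ok.sum() < 3:
            warnings.warn(
                f"session {rat}/{sid}: <3 initiation times, not detrended",
                stacklevel=2,
            )
            continue
        ti = g.loc[ok, "trial_initiation_time"].to_numpy(dtype=float)
        tn = g.loc[ok, "trial_index"].to_numpy(dtype=float)
        z = (tn - tn.mean()) / (tn.std(ddof=0) if tn.std(ddof=0) > 0 else 1.0)
        fit = sm.OLS(ti, sm.add_constant(z)).fit()
        out.loc[g.index[ok], "ti_detrended"] = ti - fit.fittedvalues + ti.mean()
    return out


# ----------------------------------------------------------------------
# block sensitivity
# ----------------------------------------------------------------------

def _ranksum(a: np.ndarray, b: np.ndarray) -> float:
    """Wilcoxon rank-sum p: exact for small samples, else normal approx
    with continuity correction."""
    if a.size == 0 or b.size == 0:
        return np.nan
    method = "exact" if min(a.size, b.size) <= 20 else "asymptotic"
    return float(
        st.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue
    )


def block_sensitivity(trials: pd.DataFrame, measure: str = "wait") -> pd.DataFrame:
    """Per-rat high/low block ratio with a rank-sum test.

    ``measure="wait"``: mean wait on 20-μL catch trials, high block / low
    block.  ``measure="initiation"``: mean initiation time over all trials,
    high / low.  Ratios below 1 mean faster/less-patient behavior in high
    blocks.
    """
    rows = []
    for rat, g in trials.groupby("rat_id", sort=False):
        if measure == "wait":
            sel = g.loc[
                g["is_catch"].astype(bool)
                & g["wait_time"].notna()
                & (g["reward_offer"] == 20.0)
            ]
            col = "wait_time"
        elif measure == "initiation":
            col = "ti_detrended" if "ti_detrended" in g else "trial_initiation_time"
            sel = g.loc[g[col].notna()]
        else:
            raise ValueError(f"unknown measure {measure!r}")
        hi = sel.loc[sel["block"] == "high", col].to_numpy(dtype=float)
        lo = sel.loc[sel["block"] == "low", col].to_numpy(dtype=float)
        if hi.size == 0 or lo.size == 0:
            raise EmptyDataError(
                f"rat {rat}: no {measure} observations in high and/or low blocks"
            )
        rows.append(
            {
                "rat_id": rat,
                "ratio": hi.mean() / lo.mean(),
                "n_high": hi.size,
                "n_low": lo.size,
                "p_ranksum": _ranksum(hi, lo),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# transition dynamics
# ----------------------------------------------------------------------

@dataclass
class TransitionCurve:
    """Δ z-scored behavior aligned to a block transition.

    Offset 0 is the first trial of the new block; negative offsets reach
    into the previous block.  ``values`` is the across-rat average of the
    smoothed per-rat curves; ``per_rat`` holds the smoothed per-rat curves
    (rats × offsets).
    """

    transition: str
    offsets: np.ndarray
    values: np.ndarray
    per_rat: np.ndarray
    rat_ids: list
    window: int = 10

    def plot(self, ax=None):  # pragma: no cover - convenience only
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.axvline(0, color="0.7", ls="--")
        ax.plot(self.offsets, self.values)
        ax.set_xlabel("trial from transition")
        ax.set_ylabel("Δ z-scored behavior")
        ax.set_title(self.transition)
        return ax


def _smooth(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    return (
        pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()
    )


def _zscore_for_measure(trials: pd.DataFrame, measure: str) -> pd.Series:
    """Per-rat z-scored behavior: wait z-scored per reward volume on catch
    trials; initiation times detrended then z-scored over all trials."""
    z = pd.Series(np.nan, index=trials.index)
    if measure == "wait":
        sel = trials["is_catch"].astype(bool) & trials["wait_time"].notna()
        grp = trials.loc[sel].groupby(["rat_id", "reward_offer"], sort=False)[
            "wait_time"
        ]
        zz = (trials.loc[sel, "wait_time"] - grp.transform("mean")) / grp.transform(
            "std"
        )
        # Δ relative to the volume's average z (zero by construction)
        z.loc[sel] = zz - zz.groupby(
            [trials.loc[sel, "rat_id"], trials.loc[sel, "reward_offer"]]
        ).transform("mean")
    elif measure == "initiation":
        df = trials
        if "ti_detrended" not in df:
            df = detrend_initiation_times(df)
        sel = df["ti_detrended"].notna()
        grp = df.loc[sel].groupby("rat_id", sort=False)["ti_detrended"]
        z.loc[sel] = (df.loc[sel, "ti_detrended"] - grp.transform("mean")) / grp.transform("std")
    else:
        raise ValueError(f"unknown measure {measure!r}")
    return z


def transition_dynamics(
    trials: pd.DataFrame,
    transition: str,
    measure: str = "wait",
    pre: int = 15,
    post: int = 40,
    window: int = 10,
) -> TransitionCurve:
    """Average Δ z-scored behavior around block transitions of one type.

    Wait times are z-scored per (rat, volume) on catch trials; initiation
    times are detrended per session and z-scored per rat over all trials.
    Violation trials occupy offsets but contribute a value only where the
    measure is observed.  Per-rat curves are smoothed with a ``window``-point
    centered moving average before averaging across rats.
    """
    if transition not in TRANSITIONS:
        raise ValueError(f"unknown transition {transition!r}")
    frm, to = transition.split("->")
    z = _zscore_for_measure(trials, measure)
    offsets = np.arange(-pre, post + 1)
    per_rat, rat_ids = [], []
    for rat, g in trials.groupby("rat_id", sort=False):
        acc = []
        for _, s in g.groupby("session_id", sort=False):
            blocks = s["block"].to_numpy()
            zs = z.loc[s.index].to_numpy(dtype=float)
            change = np.flatnonzero(blocks[1:] != blocks[:-1]) + 1
            for c in change:
                if blocks[c - 1] == frm and blocks[c] == to:
                    row = np.full(offsets.size, np.nan)
                    lo = max(0, c - pre)
                    hi = min(len(blocks), c + post + 1)
                    row[(lo - c) + pre : (hi - c) + pre] = zs[lo:hi]
                    acc.append(row)
        if acc:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                mean_curve = np.nanmean(np.vstack(acc), axis=0)
            per_rat.append(_smooth(mean_curve, window))
            rat_ids.append(rat)
    if not per_rat:
        raise EmptyDataError(f"no {transition} transitions found")
    per_rat = np.vstack(per_rat)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(per_rat, axis=0)
    return TransitionCurve(
        transition=transition,
        offsets=offsets,
        values=values,
        per_rat=per_rat,
        rat_ids=rat_ids,
        window=window,
    )


def overshoot(curve: TransitionCurve, at: int = 20) -> float:
    """Transient excess after a transition: max post-transition value minus
    the value ``at`` trials in (default 20)."""
    post = curve.offsets >= 0
    if curve.offsets.max() < at:
        raise ValueError(
            f"curve must extend at least {at} trials past the transition"
        )
    vals = curve.values[post]
    return float(np.nanmax(vals) - curve.values[curve.offsets == at][0])


# ----------------------------------------------------------------------
# logistic fits and shuffle test
# ----------------------------------------------------------------------

@dataclass
class LogisticParams:
    """4-parameter logistic y = A + (D − A)/(1 + exp(−C (x − x0)))."""

    A: float
    D_log: float
    C_inv: float
    x0: float
    sse: float = np.nan

    def __call__(self, x):
        return self.A + (self.D_log - self.A) / (
            1.0 + np.exp(-self.C_inv * (np.asarray(x, dtype=float) - self.x0))
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.A, self.D_log, self.C_inv, self.x0])


def fit_logistic(x: np.ndarray, y: np.ndarray, n_starts: int = 5) -> LogisticParams:
    """Least-squares 4-parameter logistic fit, constrained to A ≤ D.

    Parametrized as (A, D−A ≥ 0, C, x0) so the asymptote ordering is a bound
    rather than a penalty; a small deterministic grid of starts guards
    against the sign ambiguity of C.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise FittingError("need at least 5 points for a 4-parameter logistic")
    ymin, ymax = float(y.min()), float(y.max())
    span = max(ymax - ymin, 1e-9)
    xspan = max(float(x.max() - x.min()), 1e-9)

    def resid(p):
        A, s, C, x0 = p
        return A + s / (1.0 + np.exp(-C * (x - x0))) - y

    lo = [ymin - 2 * span, 0.0, -50.0 / xspan, x.min() - xspan]
    hi = [ymax + 2 * span, 4 * span, 50.0 / xspan, x.max() + xspan]
    q = np.quantile(x, [0.25, 0.5, 0.75])
    starts = [
        (ymin, span, c0, xq)
        for c0 in (4.0 / xspan, -4.0 / xspan, 0.5 / xspan)
        for xq in q
    ][:n_starts] or [(ymin, span, 4.0 / xspan, q[1])]
    best = None
    for s0 in starts:
        try:
            r = least_squares(resid, s0, bounds=(lo, hi), max_nfev=400)
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise FittingError("logistic fit failed from every start")
    A, s, C, x0 = best.x
    return LogisticParams(
        A=float(A), D_log=float(A + s), C_inv=float(C), x0=float(x0),
        sse=float(2 * best.cost),
    )


def shuffle_test_logistic(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    x: np.ndarray | None = None,
    n_shuffles: int = 500,
    rng: np.random.Generator | None = None,
    n_starts: int = 3,
) -> pd.DataFrame:
    """Label-permutation test on logistic parameters of two groups' curves.

    Fits the logistic to each group's average curve, then builds a null by
    reshuffling group labels ``n_shuffles`` times and refitting.  Returns,
    per parameter, the observed difference (a − b), the one-tailed upper
    p-value P(null ≥ observed) and the null CDF at the observed value.
    """
    a = np.atleast_2d(np.asarray(curves_a, dtype=float))
    b = np.atleast_2d(np.asarray(curves_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 curves")
    if x is None:
        x = np.arange(a.shape[1])
    rng = np.random.default_rng() if rng is None else rng

    def group_params(ca, cb):
        pa = fit_logistic(x, np.nanmean(ca, axis=0), n_starts=n_starts)
        pb = fit_logistic(x, np.nanmean(cb, axis=0), n_starts=n_starts)
        return pa.as_array() - pb.as_array()

    obs = group_params(a, b)
    pooled = np.vstack([a, b])
    na = a.shape[0]
    null = np.empty((n_shuffles, 4))
    for i in range(n_shuffles):
        perm = rng.permutation(pooled.shape[0])
        null[i] = group_params(pooled[perm[:na]], pooled[perm[na:]])
    p_upper = (1.0 + np.sum(null >= obs, axis=0)) / (n_shuffles + 1.0)
    cdf = (1.0 + np.sum(null <= obs, axis=0)) / (n_shuffles + 1.0)
    return pd.DataFrame(
        {
            "parameter": ["A", "D_log", "C_inv", "x0"],
            "observed_diff": obs,
            "p_upper": p_upper,
            "null_cdf": cdf,
            "n_shuffles": n_shuffles,
        }
    )


# ----------------------------------------------------------------------
# trial-history effects
# ----------------------------------------------------------------------

def previous_offer_sensitivity(
    trials: pd.DataFrame, measure: str = "wait"
) -> pd.DataFrame:
    """Sensitivity of 20-μL mixed-block behavior to the previous offer.

    Per rat: z-score the qualifying trials (20-μL catch waits, or all 20-μL
    initiation times, mixed blocks only), split by whether the previous
    trial's offer was below or above 20 μL, and report
    Δ = mean(prev < 20) − mean(prev > 20) with a rank-sum p.
    """
    rows = []
    for rat, g in trials.groupby("rat_id", sort=False):
        lt, gt = [], []
        for _, s in g.groupby("session_id", sort=False):
            offers = s["reward_offer"].to_numpy(dtype=float)
            prev = np.concatenate([[np.nan], offers[:-1]])
            mixed = (s["block"] == "mixed").to_numpy()
            if measure == "wait":
                val = s["wait_time"].where(s["is_catch"].astype(bool)).to_numpy(dtype=float)
            elif measure == "initiation":
                col = "ti_detrended" if "ti_detrended" in s else "trial_initiation_time"
                val = s[col].to_numpy(dtype=float)
            else:
                raise ValueError(f"unknown measure {measure!r}")
            sel = mixed & (offers == 20.0) & np.isfinite(val) & np.isfinite(prev)
            lt.append(val[sel & (prev < 20.0)])
            gt.append(val[sel & (prev > 20.0)])
        lt = np.concatenate(lt) if lt else np.array([])
        gt = np.concatenate(gt) if gt else np.array([])
        if lt.size == 0 or gt.size == 0:
            raise EmptyDataError(
                f"rat {rat}: no qualifying 20-μL mixed-block trials on both sides"
            )
        allv = np.concatenate([lt, gt])
        mu, sd = allv.mean(), allv.std(ddof=1)
        zl, zg = (lt - mu) / sd, (gt - mu) / sd
        rows.append(
            {
                "rat_id": rat,
                "delta": zl.mean() - zg.mean(),
                "n_prev_lt": lt.size,
                "n_prev_gt": gt.size,
                "p_ranksum": _ranksum(zl, zg),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class HistoryRegressionResult:
    """Trial-history regression kernel for one rat.

    ``coefficients`` follow the zeroing rule (everything from the first
    non-significant coefficient on is exactly 0); ``raw_coefficients`` are
    the unmodified OLS estimates.  ``current_offer_coef`` is present for the
    wait-time regression only.  ``tau_hist = 0`` whenever every previous-
    trial coefficient is 0.
    """

    measure: str
    current_offer_coef: float | None
    coefficients: np.ndarray  # previous 1..n_prev, zeroing rule applied
    raw_coefficients: np.ndarray
    conf_int: np.ndarray  # (n_coef, 2) for the scanned coefficients
    first_nonsig: int | None
    D_hist: float
    tau_hist: float
    nobs: int


def fit_exponential_decay(coefs: np.ndarray) -> tuple[float, float]:
    """Fit y = D·exp(−x/τ) to the previous-trial coefficients.

    x = 0 indexes the most recent previous trial, so D is the one-back
    coefficient and τ is in units of trials.  All-zero coefficients report
    τ = 0 by convention.
    """
    y = np.asarray(coefs, dtype=float)
    x = np.arange(y.size, dtype=float)
    if np.allclose(y, 0.0):
        return 0.0, 0.0

    def resid(p):
        return p[0] * np.exp(-x / p[1]) - y

    best = None
    for tau0 in (0.5, 2.0, 8.0):
        try:
            r = least_squares(
                resid,
                (float(y[0]) if y[0] != 0 else float(np.max(np.abs(y))), tau0),
                bounds=([-np.inf, 1e-8], [np.inf, 1e3]),
                max_nfev=400,
            )
        except Exception:
            continue
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        return 0.0, 0.0
    return float(best.x[0]), float(best.x[1])


def _lagged_regressors(
    s: pd.DataFrame, measure: str, n_prev: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-session design pieces: current log2 offer and lagged offers.

    Offers are log2-linearized.  For the initiation regression, violation
    and catch trials enter the history with a regressor value of 0 (no
    reward was received); for the wait regression the offered volume is used
    on every trial, violations included.  Offers from a different block are
    NaN so any row reaching across a block boundary is dropped.
    """
    offers = s["reward_offer"].to_numpy(dtype=float)
    logr = np.log2(offers)
    blocks = s["block"].to_numpy()
    if measure == "initiation":
        unrewarded = (
            s["is_violation"].astype(bool) | s["is_catch"].astype(bool)
        ).to_numpy()
        logr = np.where(unrewarded, 0.0, logr)
    lags = np.full((len(s), n_prev), np.nan)
    for k in range(1, n_prev + 1):
        lagged = np.concatenate([np.full(k, np.nan), logr[:-k]])
        same_block = np.concatenate([np.full(k, False), blocks[:-k] == blocks[k:]])
        lags[:, k - 1] = np.where(same_block, lagged, np.nan)
    return np.log2(offers), lags


def history_regression(
    trials: pd.DataFrame, measure: str = "wait", n_prev: int = 9
) -> HistoryRegressionResult:
    """Regress mixed-block behavior on the current and previous 9 offers.

    Wait times (z-scored catch trials): regressors are the current offer and
    the previous ``n_prev`` log2 offers.  Initiation times (z-scored, all
    mixed-block trials): previous offers only, with violation/catch rewards
    coded 0.  After OLS, the first coefficient whose 95% CI covers 0 — and
    all later ones — are set to 0, and a negative exponential is fit to the
    previous-trial kernel.

    Operates on a single rat's trials.
    """
    if trials["rat_id"].nunique() > 1:
        raise ValueError("history_regression expects a single rat's trials")
    ys, Xs = [], []
    for _, s in trials.groupby("session_id", sort=False):
        cur, lags = _lagged_regressors(s, measure, n_prev)
        mixed = (s["block"] == "mixed").to_numpy()
        if measure == "wait":
            val = s["wait_time"].where(s["is_catch"].astype(bool)).to_numpy(dtype=float)
            X = np.column_stack([cur, lags])
        elif measure == "initiation":
            col = "ti_detrended" if "ti_detrended" in s else "trial_initiation_time"
            val = s[col].to_numpy(dtype=float)
            X = lags
        else:
            raise ValueError(f"unknown measure {measure!r}")
        sel = mixed & np.isfinite(val) & np.all(np.isfinite(X), axis=1)
        ys.append(val[sel])
        Xs.append(X[sel])
    y = np.concatenate(ys)
    X = np.vstack(Xs)
    n_reg = X.shape[1] + 1
    if y.size < 10 * n_reg:
        raise EmptyDataError(
            f"history regression needs ≥ {10 * n_reg} usable rows, got {y.size}"
        )
    y = (y - y.mean()) / y.std(ddof=1)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    coefs = fit.params[1:]  # drop intercept
    ci = fit.conf_int(alpha=0.05)[1:]
    nonsig = (ci[:, 0] <= 0) & (ci[:, 1] >= 0)
    first = int(np.argmax(nonsig)) if nonsig.any() else None
    zeroed = coefs.copy()
    if first is not None:
        zeroed[first:] = 0.0
    if measure == "wait":
        cur_coef = float(zeroed[0])
        prev = zeroed[1:]
        raw_prev = coefs[1:]
    else:
        cur_coef = None
        prev = zeroed
        raw_prev = coefs
    D_hist, tau_hist = fit_exponential_decay(prev)
    return HistoryRegressionResult(
        measure=measure,
        current_offer_coef=cur_coef,
        coefficients=prev,
        raw_coefficients=raw_prev,
        conf_int=ci,
        first_nonsig=first,
        D_hist=D_hist,
        tau_hist=tau_hist,
        nobs=int(y.size),
    )


# ----------------------------------------------------------------------
# learning dynamics
# ----------------------------------------------------------------------

def _moving_median_outliers(x: np.ndarray, window: int = 5, thresh: float = 3.0) -> np.ndarray:
    """Flags where |x − moving median| > thresh · scaled moving MAD.

    Mirrors the movmedian variant of MATLAB's isoutlier: centered windows,
    MAD scaled by 1.4826 for normal consistency.
    """
    x = np.asarray(x, dtype=float)
    s = pd.Series(x)
    roll = s.rolling(window, center=True, min_periods=1)
    med = roll.median().to_numpy()
    mad = roll.apply(
        lambda w: np.nanmedian(np.abs(w - np.nanmedian(w))), raw=True
    ).to_numpy()
    scaled = 1.4826 * mad
    with np.errstate(invalid="ignore"):
        return np.abs(x - med) > thresh * scaled


def learning_dynamics(trials: pd.DataFrame, smooth_window: int = 5) -> dict:
    """Across-session emergence of block and history effects.

    Per rat: session pairs' wait/initiation high-low ratios; per-session
    regression of wait on (current reward, block code 1/2/3) and of
    initiation time on the previous reward; coefficients smoothed with a
    5-session moving average, then outliers (3 scaled MADs from a 5-point
    moving median) set to NaN.

    Returns ``{"pair_ratios": ..., "coefficients": ...}`` DataFrames.
    """
    from .inference import BLOCK_CODE

    ratio_rows, coef_rows = [], []
    for rat, g in trials.groupby("rat_id", sort=False):
        sessions = list(g.groupby("session_id", sort=False))
        if len(sessions) < 2:
            raise EmptyDataError(f"rat {rat}: learning dynamics needs ≥ 2 sessions")
        # session pairs
        for p in range(len(sessions) // 2):
            pair = pd.concat([sessions[2 * p][1], sessions[2 * p + 1][1]])
            row = {"rat_id": rat, "pair": p}
            for measure in ("wait", "initiation"):
                try:
                    row[f"{measure}_ratio"] = block_sensitivity(pair, measure)[
                        "ratio"
                    ].iloc[0]
                except EmptyDataError:
                    row[f"{measure}_ratio"] = np.nan
            ratio_rows.append(row)
        # per-session regressions
        wait_c, ti_c = [], []
        for sid, s in sessions:
            catch = s.loc[s["is_catch"].astype(bool) & s["wait_time"].notna()]
            if len(catch) >= 5 and catch["reward_offer"].nunique() > 1:
                X = np.column_stack(
                    [
                        catch["reward_offer"].to_numpy(dtype=float),
                        catch["block"].map(BLOCK_CODE).to_numpy(dtype=float),
                    ]
                )
                f = sm.OLS(catch["wait_time"].to_numpy(dtype=float), sm.add_constant(X)).fit()
                wait_c.append((sid, f.params[1], f.params[2]))
            else:
                wait_c.append((sid, np.nan, np.nan))
            ti = s["trial_initiation_time"].to_numpy(dtype=float)
            prev_r = np.concatenate([[np.nan], s["reward_offer"].to_numpy(dtype=float)[:-1]])
            ok = np.isfinite(ti) & np.isfinite(prev_r)
            if ok.sum() >= 5:
                f = sm.OLS(ti[ok], sm.add_constant(prev_r[ok])).fit()
                ti_c.append((sid, f.params[1]))
            else:
                ti_c.append((sid, np.nan))
        session_ids = [sid for sid, _ in sessions]
        for name, series in (
            ("wait_reward", np.array([c[1] for c in wait_c], dtype=float)),
            ("wait_block", np.array([c[2] for c in wait_c], dtype=float)),
            ("ti_prev_reward", np.array([c[1] for c in ti_c], dtype=float)),
        ):
            smoothed = _smooth(series, smooth_window)
            out = _moving_median_outliers(smoothed, window=5, thresh=3.0)
            cleaned = np.where(out, np.nan, smoothed)
            for i, sid in enumerate(session_ids):
                coef_rows.append(
                    {
                        "rat_id": rat,
                        "session_id": sid,
                        "coefficient": name,
                        "raw": series[i],
                        "smoothed": smoothed[i],
                        "cleaned": cleaned[i],
                    }
                )
    return {
        "pair_ratios": pd.DataFrame(ratio_rows),
        "coefficients": pd.DataFrame(coef_rows),
    }


# ----------------------------------------------------------------------
# misinference
# ----------------------------------------------------------------------

def misinference_trials(trials: pd.DataFrame, trace) -> pd.Series:
    """Flag mixed-block trials whose MAP block is not mixed.

    ``trace`` is the hidden-state model's forward pass over the same trials
    (same row order) — either a :class:`~tempwager.values.ValueTrace` or a
    fitted :class:`~tempwager.fitting.WaitTimeResults` of an inference-based
    model, whose filter trace is reused.  Returns a Series with values
    ``"none"``, ``"misinferred-low"`` or ``"misinferred-high"``.
    """
    if hasattr(trace, "params_dict"):  # a fitted WaitTimeResults
        from .inference import BLOCKS, map_block_indices
        from .values import ValueModelParams, run_value_model

        res = trace
        pd_ = res.params_dict
        if "kappa_low" not in pd_:
            raise ValueError("misinference needs an inference-based model fit")
        model = (
            "suboptimal_inferential" if "lambda_mix" in pd_ else "inferential"
        )
        params = ValueModelParams(
            kappa_low=pd_["kappa_low"],
            kappa_mixed=pd_["kappa_mixed"],
            kappa_high=pd_["kappa_high"],
            lambda_mix=pd_.get("lambda_mix", 1.0),
        )
        labels = np.concatenate(
            [
                run_value_model(
                    g,
                    model,
                    params,
                    H0=res.model.hazard_rate,
                    init=res.model.init_posterior,
                    update_on_violations=res.model.update_on_violations,
                ).map_block
                for _, g in trials.groupby(["rat_id", "session_id"], sort=False)
            ]
        )
    else:
        if len(trace) != len(trials):
            raise ValueError("trace and trials length mismatch")
        labels = np.asarray(trace.map_block, dtype=object)
    mixed = (trials["block"] == "mixed").to_numpy()
    out = np.where(
        mixed & (labels == "high"),
        "misinferred-high",
        np.where(mixed & (labels == "low"), "misinferred-low", "none"),
    )
    return pd.Series(out, index=trials.index, name="misinference")
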