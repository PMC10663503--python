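"""Per-trial value of the environment (opportunity cost, κ).

Four ways of computing κ, the scalar reward rate of the environment against
which waiting is weighed:

``inferential``
    Most-Likely-State approximation: run the Bayes filter and take the fixed
    κ associated with the MAP block (one of kappa_low / kappa_mixed /
    kappa_high).
``belief_state``
    Posterior-weighted average of the three block κ's.
``suboptimal_inferential``
    Same as ``inferential`` but the filter's prior is λ-blended with a flat
    prior (``lambda_mix``).
``retrospective``
    Temporal-difference learning: κ is a recency-weighted average of offered
    rewards, ``κ_{t+1} = κ_t + α_t (r_t − κ_t)`` with a dynamic learning rate
    ``α_t = G_t · α_0``.  The gain G_t is either 1 (static), the unsigned
    reward prediction error, or — the headline variant — inversely related to
    the trial-by-trial change in the mixed-block posterior of a parallel
    ideal-observer filter, ``G_t = 1 / (1 − |Δ p_mixed|)``.

κ carries units of μL/s so that κ·τ is commensurate with the offered volume;
rewards entering the retrospective update are divided by ``reward_timescale``
(seconds) to share those units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import (
    BLOCKS,
    DEFAULT_HAZARD,
    map_block_indices,
    run_filter,
)

try:  # pragma: no cover
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


VALUE_MODELS = (
    "inferential",
    "belief_state",
    "suboptimal_inferential",
    "retrospective",
)

GAIN_MODES = ("belief_change", "static", "abs_rpe")


@dataclass
class ValueModelParams:
    """Parameters shared by the four value models.

    kappa_low / kappa_mixed / kappa_high : μL/s
        Fixed block values (inferential, belief-state and λ models).
    lambda_mix : fraction in [0, 1]
        Prior quality for the sub-optimal inferential model.
    alpha0 : base learning rate in (0, 1]
        Retrospective model.
    kappa_init : μL/s
        Retrospective κ at session start.
    gain_mode : {"belief_change", "static", "abs_rpe"}
        Learning-rate gain variant.
    gain_cap : maximum G
        Caps ``1/(1−|Δp_mixed|)`` which diverges as |Δp| → 1.
    reward_timescale : seconds
        Divides rewards entering the retrospective update so κ is in μL/s.
    """

    kappa_low: float = 2.0
    kappa_mixed: float = 4.0
    kappa_high: float = 8.0
    lambda_mix: float = 1.0
    alpha0: float = 0.1
    kappa_init: float = 3.1
    gain_mode: str = "belief_change"
    gain_cap: float = 1000.0
    reward_timescale: float = 1.0

    def __post_init__(self):
        if min(self.kappa_low, self.kappa_mixed, self.kappa_high) <= 0:
            raise ValueError("block kappas must be positive")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ValueError("lambda_mix must lie in [0, 1]")
        if not 0.0 < self.alpha0 <= 1.0:
            raise ValueError("alpha0 must lie in (0, 1]")
        if self.gain_mode not in GAIN_MODES:
            raise ValueError(f"unknown gain_mode {self.gain_mode!r}")

    @property
    def kappa_vector(self) -> np.ndarray:
        return np.array([self.kappa_low, self.kappa_mixed, self.kappa_high])


@dataclass
class ValueTrace:
    """Per-trial output of a value model over one session.

    ``kappa`` is the value used for the wait-time decision on each trial
    (posterior including the current offer for inference-based models, the
    pre-update κ_t for the retrospective model); ``kappa_pre`` is the
    pre-offer value driving the trial-initiation decision.
    """

    kappa: np.ndarray
    kappa_pre: np.ndarray
    posterior: np.ndarray  # (n, 3) over (low, mixed, high)
    prior: np.ndarray  # (n, 3)
    map_block: np.ndarray  # block labels (strings)
    gain: np.ndarray

    def __len__(self) -> int:
        return self.kappa.size

    def to_frame(self) -> pd.DataFrame:
        """Tabular export matching the trial table row order."""
        return pd.DataFrame(
            {
                "kappa": self.kappa,
                "kappa_pre": self.kappa_pre,
                "p_low": self.posterior[:, 0],
                "p_mixed": self.posterior[:, 1],
                "p_high": self.posterior[:, 2],
                "map_block": self.map_block,
                "gain": self.gain,
            }
        )


def gain(
    posterior_t: np.ndarray,
    posterior_prev: np.ndarray,
    mode: str = "belief_change",
    rpe: float = 0.0,
    cap: float = 1000.0,
) -> float:
    """Learning-rate gain G for one trial.

    ``belief_change``: ``1 / (1 − |Δ p_mixed|)`` capped at ``cap``;
    ``static``: 1; ``abs_rpe``: |reward prediction error|.
    """
    if mode == "static":
        return 1.0
    if mode == "abs_rpe":
        return abs(float(rpe))
    if mode != "belief_change":
        raise ValueError(f"unknown gain mode {mode!r}")
    dp = abs(float(posterior_t[1]) - float(posterior_prev[1]))
    if dp >= 1.0:
        return float(cap)
    return float(min(1.0 / (1.0 - dp), cap))


def update_kappa_retrospective(
    kappa: float, reward: float, alpha0: float, G: float = 1.0
) -> float:
    """One TD update ``κ' = κ + α_eff (r − κ)`` with ``α_eff = min(G·α0, 1)``."""
    a = min(G * alpha0, 1.0)
    return kappa + a * (reward - kappa)


@njit(cache=True)
def _retro_loop(r, update, G, alpha0, kappa_init, abs_rpe_mode, cap):  # pragma: no cover
    n = r.shape[0]
    kap = np.empty(n)
    g_out = np.empty(n)
    k = kappa_init
    for t in range(n):
        kap[t] = k
        if update[t]:
            if abs_rpe_mode:
                g = abs(r[t] - k)
                if g > cap:
                    g = cap
            else:
                g = G[t]
            a = g * alpha0
            if a > 1.0:
                a = 1.0
            g_out[t] = g
            k = k + a * (r[t] - k)
        else:
            g_out[t] = 1.0
    return kap, g_out


def belief_change_gain(posterior: np.ndarray, cap: float = 1000.0) -> np.ndarray:
    """Per-trial G from an (n, 3) posterior trace; G[0] = 1 (no previous)."""
    p_mix = posterior[:, 1]
    dp = np.abs(np.diff(p_mix, prepend=p_mix[:1]))
    with np.errstate(divide="ignore"):
        g = 1.0 / (1.0 - dp)
    return np.minimum(np.where(np.isfinite(g), g, cap), cap)


def run_value_model(
    trials: pd.DataFrame,
    model: str,
    params: ValueModelParams,
    H0: float = DEFAULT_HAZARD,
    init: str = "mixed",
    update_on_violations: bool = True,
    retrospective_skip_violations: bool = True,
    zero_unrewarded: bool = False,
) -> ValueTrace:
    """Forward-run a value model over one time-ordered session.

    Parameters
    ----------
    trials
        Trial table for a single session (rows in temporal order) with at
        least ``reward_offer`` and ``is_violation`` columns.
    model
        One of ``inferential``, ``belief_state``, ``suboptimal_inferential``,
        ``retrospective``.
    update_on_violations
        Whether the Bayes filter updates on the repeated offers of violation
        trials (default: it does).
    retrospective_skip_violations
        Whether the retrospective κ skips violation trials (default: it does;
        only completed-trial offers feed the running average).
    zero_unrewarded
        Retrospective only: code violation and catch rewards as 0 instead of
        skipping them (mirrors the regression convention).
    """
    if model not in VALUE_MODELS:
        raise ValueError(
            f"unknown value model {model!r}; expected one of {VALUE_MODELS}"
        )
    offers = np.asarray(trials["reward_offer"], dtype=float)
    if "is_violation" in trials:
        viol = np.asarray(trials["is_violation"], dtype=bool)
    else:
        viol = np.zeros(offers.size, dtype=bool)
    filt_mask = np.ones(offers.size, dtype=bool) if update_on_violations else ~viol

    lam = params.lambda_mix if model == "suboptimal_inferential" else 1.0
    priors, posts = run_filter(
        offers, H0=H0, lambda_mix=lam, init=init, update_mask=filt_mask
    )
    map_idx = map_block_indices(posts)
    map_labels = np.asarray(BLOCKS, dtype=object)[map_idx]
    kv = params.kappa_vector

    if model in ("inferential", "suboptimal_inferential"):
        kappa = kv[map_idx]
        kappa_pre = kv[map_block_indices(priors)]
        g = np.ones(offers.size)
    elif model == "belief_state":
        kappa = posts @ kv
        kappa_pre = priors @ kv
        g = np.ones(offers.size)
    else:  # retrospective
        r = offers / params.reward_timescale
        if zero_unrewarded:
            is_catch = (
                np.asarray(trials["is_catch"], dtype=bool)
                if "is_catch" in trials
                else np.zeros(offers.size, dtype=bool)
            )
            r = np.where(viol | is_catch, 0.0, r)
            upd = np.ones(offers.size, dtype=bool)
        else:
            upd = ~viol if retrospective_skip_violations else np.ones(
                offers.size, dtype=bool
            )
        if params.gain_mode == "belief_change":
            # parallel ideal-observer filter supplies the gain
            if lam != 1.0 or not filt_mask.all():
                _, opt_posts = run_filter(offers, H0=H0, lambda_mix=1.0, init=init)
            else:
                opt_posts = posts
            G = belief_change_gain(opt_posts, cap=params.gain_cap)
        elif params.gain_mode == "static":
            G = np.ones(offers.size)
        else:
            G = np.zeros(offers.size)  # filled inside the loop
        kappa, g = _retro_loop(
            np.ascontiguousarray(r),
            upd,
            np.ascontiguousarray(G, dtype=np.float64),
            float(params.alpha0),
            float(params.kappa_init),
            params.gain_mode == "abs_rpe",
            float(params.gain_cap),
        )
        kappa_pre = kappa  # κ_t predates the trial-t offer by construction

    return ValueTrace(
        kappa=np.asarray(kappa, dtype=float),
        kappa_pre=np.asarray(kappa_pre, dtype=float),
        posterior=posts,
        prior=priors,
        map_block=map_labels,
        gain=np.asarray(g, dtype=float),
    )


def kappa_inferential(posterior: np.ndarray, params: ValueModelParams) -> float:
    """κ of the MAP block (Most Likely State rule)."""
    from .inference import map_block as _map

    return float(params.kappa_vector[BLOCKS.index(_map(posterior))])


def kappa_belief_state(posterior: np.ndarray, params: ValueModelParams) -> float:
    """Posterior-weighted average of the block κ's."""
    return float(np.asarray(posterior, dtype=float) @ params.kappa_vector)
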