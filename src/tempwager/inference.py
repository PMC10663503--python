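"""Bayesian hidden-state (block) inference.

The environment alternates between three uncued blocks -- ``low``, ``mixed``
and ``high`` -- that determine which reward volumes can be offered.  An ideal
observer tracks a posterior over the current block by combining

- a *likelihood* of each offered reward under each block (uniform over the
  block's allowed volumes),
- a *transition (hazard) matrix* encoding that blocks last ~40 completed
  trials and that low and high blocks never follow one another directly,

via the standard recursive Bayes filter: propagate yesterday's posterior
through the hazard matrix to get today's prior, multiply by the likelihood of
today's offer, renormalize.  A sub-optimality knob ``lambda_mix`` blends the
propagated prior with a flat prior (``lambda_mix=1`` is the ideal observer,
``lambda_mix=0`` ignores all history).

Blocks are indexed ``0=low, 1=mixed, 2=high`` throughout.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


#: canonical reward volumes, μL
REWARDS = (5.0, 10.0, 20.0, 40.0, 80.0)

#: block labels in canonical index order (categorical coding 1, 2, 3)
BLOCKS = ("low", "mixed", "high")

BLOCK_INDEX = {"low": 0, "mixed": 1, "high": 2}
BLOCK_CODE = {"low": 1, "mixed": 2, "high": 3}

#: reward volumes available in each block
BLOCK_REWARDS = {
    "low": (5.0, 10.0, 20.0),
    "mixed": REWARDS,
    "high": (20.0, 40.0, 80.0),
}

#: per-trial block transition probability implied by the 40-trial block length
DEFAULT_HAZARD = 1.0 / 40.0

# MAP tie-break preference: mixed, then low, then high
_TIE_ORDER = np.array([1, 0, 2])


def _likelihood_row(reward: float) -> np.ndarray:
    """Likelihood vector P(reward | block) over (low, mixed, high)."""
    r = float(reward)
    if r not in REWARDS:
        raise ValueError(f"reward {reward} not in the task set {REWARDS}")
    low = 1.0 / 3.0 if r in BLOCK_REWARDS["low"] else 0.0
    high = 1.0 / 3.0 if r in BLOCK_REWARDS["high"] else 0.0
    return np.array([low, 0.2, high])


def reward_likelihood(reward: float, block: str) -> float:
    """P(reward | block): uniform over the block's allowed volume set.

    Low and high blocks draw uniformly from their three volumes (1/3 each,
    0 elsewhere); mixed blocks draw uniformly from all five (1/5 each).
    """
    if block not in BLOCK_INDEX:
        raise ValueError(f"unknown block {block!r}")
    return float(_likelihood_row(reward)[BLOCK_INDEX[block]])


def likelihood_matrix(rewards: np.ndarray) -> np.ndarray:
    """(n, 3) matrix of P(reward_t | block) rows for a reward sequence."""
    rewards = np.asarray(rewards, dtype=float)
    out = np.empty((rewards.size, 3))
    for i, r in enumerate(rewards.ravel()):
        out[i] = _likelihood_row(r)
    return out


def build_hazard_matrix(H0: float = DEFAULT_HAZARD) -> np.ndarray:
    """Block transition matrix, rows = previous block, columns = next block.

    The low column is (1-H0, H0, 0) for previous (low, mixed, high); the high
    column follows by low<->high symmetry and the mixed column makes each row
    sum to one, giving a doubly stochastic matrix with
    ``h[mixed][mixed] = 1 - 2*H0``.
    """
    if not 0.0 < H0 < 0.5:
        raise ValueError(f"H0 must lie in (0, 0.5), got {H0}")
    return np.array(
        [
            [1.0 - H0, H0, 0.0],
            [H0, 1.0 - 2.0 * H0, H0],
            [0.0, H0, 1.0 - H0],
        ]
    )


def _check_posterior(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,) or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"not a probability vector over 3 blocks: {p}")
    return p


def propagate_prior(posterior_prev: np.ndarray, hazard: np.ndarray) -> np.ndarray:
    """One-step prior: marginalize the previous posterior over the hazard.

    ``prior[b] = sum_b' hazard[b', b] * posterior_prev[b']``
    """
    p = _check_posterior(posterior_prev)
    return hazard.T @ p


def update_posterior(prior: np.ndarray, reward: float) -> np.ndarray:
    """Bayes update: posterior ∝ prior × P(reward | block), renormalized."""
    prior = np.asarray(prior, dtype=float)
    u = prior * _likelihood_row(reward)
    s = u.sum()
    if s <= 0.0:
        raise FloatingPointError(
            "posterior normalizer is zero: the prior excludes every block "
            "consistent with the observed reward"
        )
    return u / s


def suboptimal_prior(optimal_prior: np.ndarray, lambda_mix: float) -> np.ndarray:
    """Blend the propagated prior with a flat prior.

    ``lambda_mix=1`` returns the optimal prior unchanged; ``lambda_mix=0``
    returns the uninformative (1/3, 1/3, 1/3) prior.
    """
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValueError(f"lambda_mix must lie in [0, 1], got {lambda_mix}")
    optimal_prior = np.asarray(optimal_prior, dtype=float)
    return lambda_mix * optimal_prior + (1.0 - lambda_mix) / 3.0


def map_block(posterior: np.ndarray) -> str:
    """Most-likely block (MAP), ties broken in favor of mixed, then low."""
    p = _check_posterior(posterior)
    return BLOCKS[int(_TIE_ORDER[np.argmax(p[_TIE_ORDER])])]


def map_block_indices(posterior: np.ndarray) -> np.ndarray:
    """Vectorized MAP over an (n, 3) posterior array -> block indices."""
    p = np.asarray(posterior, dtype=float)
    return _TIE_ORDER[np.argmax(p[:, _TIE_ORDER], axis=1)]


@njit(cache=True)
def _filter_loop(lik, hazard_T, lam, p0, update):  # pragma: no cover - numba
    n = lik.shape[0]
    priors = np.empty((n, 3))
    posts = np.empty((n, 3))
    p = p0.copy()
    flat = 1.0 / 3.0
    for t in range(n):
        if update[t]:
            pr = hazard_T @ p
            pr = lam * pr + (1.0 - lam) * flat
            u = pr * lik[t]
            s = u[0] + u[1] + u[2]
            if s <= 0.0:
                for j in range(3):
                    priors[t, j] = np.nan
                    posts[t, j] = np.nan
                return priors, posts
            p = u / s
            priors[t] = pr
        else:
            priors[t] = p
        posts[t] = p
    return priors, posts


def run_filter(
    rewards: np.ndarray,
    H0: float = DEFAULT_HAZARD,
    lambda_mix: float = 1.0,
    init: str = "mixed",
    update_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the recursive Bayes filter over one session's reward sequence.

    Parameters
    ----------
    rewards
        Offered reward per trial, time ordered, single session.
    H0
        Per-trial block hazard rate.
    lambda_mix
        Prior-quality parameter (1 = ideal observer).
    init
        Initial posterior before the first offer: ``"mixed"`` (one-hot on the
        mixed block, since every session starts in one) or ``"flat"``.
    update_mask
        Optional boolean array; trials with ``False`` (e.g. violation trials
        under a skip-violations policy) leave the belief untouched.

    Returns
    -------
    (priors, posteriors)
        Two (n, 3) arrays.  ``priors[t]`` is the (possibly λ-blended) prior
        before the trial-t offer; ``posteriors[t]`` the posterior after it.
    """
    rewards = np.asarray(rewards, dtype=float)
    if not 0.0 <= lambda_mix <= 1.0:
        raise ValueError(f"lambda_mix must lie in [0, 1], got {lambda_mix}")
    if init == "mixed":
        p0 = np.array([0.0, 1.0, 0.0])
    elif init == "flat":
        p0 = np.full(3, 1.0 / 3.0)
    else:
        raise ValueError(f"unknown init {init!r}")
    lik = likelihood_matrix(rewards)
    hazard = build_hazard_matrix(H0)
    if update_mask is None:
        update_mask = np.ones(rewards.size, dtype=np.bool_)
    else:
        update_mask = np.asarray(update_mask, dtype=np.bool_)
    priors, posts = _filter_loop(
        np.ascontiguousarray(lik),
        np.ascontiguousarray(hazard.T),
        float(lambda_mix),
        p0,
        update_mask,
    )
    if np.isnan(posts).any():
        raise FloatingPointError("posterior normalizer hit zero mid-session")
    return priors, posts
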