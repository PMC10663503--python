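"""Maximum-likelihood fitting of the wait-time models.

The centrepiece is the Model/Results pair:

>>> model = WaitTimeModel(trials, "inferential")
>>> res = model.fit(n_starts=20, seed=0)
>>> print(res.summary())

The likelihood uses catch-trial wait times only (opt-outs on rewarded-delay
trials are censored and excluded), scored under the moment-matched log-normal
noise model with the constant 8-s² variance.  Fitting is bound-constrained
quasi-Newton (L-BFGS-B, numerically estimated gradients) from ``n_starts``
random initial points drawn uniformly within the bounds; the best start wins.
The block hazard rate H0 and the reward probability C are task constants,
never fitted.

Free parameters per model:

- ``inferential`` / ``belief_state``: κ_low, κ_mixed, κ_high, D_wt
- ``lambda_inferential``: the above plus λ
- ``retrospective``: κ_init, α0, D_wt

Model comparison uses BIC = ln(n)·k + 2·nLL and AIC = 2k + 2·nLL, plus
session-blocked k-fold cross-validated test likelihoods.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .inference import build_hazard_matrix, likelihood_matrix, map_block_indices, DEFAULT_HAZARD
from .inference import _filter_loop
from .timing import WT_FLOOR, lognormal_nll
from .values import belief_change_gain

try:  # pragma: no cover
    from numba import njit
except Exception:  # pragma: no cover
    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _filter_map_multi(lik, hazT, lam, p0, update, starts):  # pragma: no cover
    """MAP block index per trial over concatenated sessions.

    ``starts`` marks session beginnings; the belief resets to ``p0`` there.
    Tie-break preference: mixed (1), then low (0), then high (2).
    """
    n = lik.shape[0]
    out = np.empty(n, dtype=np.int64)
    s_ptr = 0
    p = p0.copy()
    flat = 1.0 / 3.0
    for t in range(n):
        if s_ptr < starts.shape[0] and t == starts[s_ptr]:
            p = p0.copy()
            s_ptr += 1
        if update[t]:
            pr0 = hazT[0, 0] * p[0] + hazT[0, 1] * p[1] + hazT[0, 2] * p[2]
            pr1 = hazT[1, 0] * p[0] + hazT[1, 1] * p[1] + hazT[1, 2] * p[2]
            pr2 = hazT[2, 0] * p[0] + hazT[2, 1] * p[1] + hazT[2, 2] * p[2]
            pr0 = lam * pr0 + (1.0 - lam) * flat
            pr1 = lam * pr1 + (1.0 - lam) * flat
            pr2 = lam * pr2 + (1.0 - lam) * flat
            u0 = pr0 * lik[t, 0]
            u1 = pr1 * lik[t, 1]
            u2 = pr2 * lik[t, 2]
            s = u0 + u1 + u2
            p[0] = u0 / s
            p[1] = u1 / s
            p[2] = u2 / s
        best = 1  # mixed wins ties
        if p[0] > p[1]:
            best = 0
        if p[2] > p[best]:
            best = 2
        out[t] = best
    return out


@njit(cache=True)
def _retro_multi(r, update, G, alpha0, kappa_init, abs_rpe_mode, cap, starts):  # pragma: no cover
    """Pre-update κ_t per trial over concatenated sessions (resets at starts)."""
    n = r.shape[0]
    kap = np.empty(n)
    s_ptr = 0
    k = kappa_init
    for t in range(n):
        if s_ptr < starts.shape[0] and t == starts[s_ptr]:
            k = kappa_init
            s_ptr += 1
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
            k = k + a * (r[t] - k)
    return kap

FIT_MODELS = ("inferential", "belief_state", "lambda_inferential", "retrospective")

_PARAM_NAMES = {
    "inferential": ("kappa_low", "kappa_mixed", "kappa_high", "D_wt"),
    "belief_state": ("kappa_low", "kappa_mixed", "kappa_high", "D_wt"),
    "lambda_inferential": ("kappa_low", "kappa_mixed", "kappa_high", "D_wt", "lambda_mix"),
    "retrospective": ("kappa_init", "alpha0", "D_wt"),
}


class EmptyDataError(ValueError):
    """Raised when an operation has no qualifying trials to work with."""


class FittingError(RuntimeError):
    """Raised when no optimizer start converges."""


def information_criteria(nll: float, k: int, n: int) -> tuple[float, float]:
    """(BIC, AIC) = (ln(n)·k + 2·nLL, 2k + 2·nLL)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return float(np.log(n) * k + 2.0 * nll), float(2.0 * k + 2.0 * nll)


@dataclass
class _StackedData:
    """Concatenated-session arrays the likelihood kernels run over.

    ``starts`` holds the index of each session's first trial; the sequential
    value models reset their state there.
    """

    offers: np.ndarray
    lik: np.ndarray  # (n, 3) reward likelihoods
    viol: np.ndarray
    starts: np.ndarray
    catch_rows: np.ndarray  # indices of scored (catch, wait observed) trials
    wait_obs: np.ndarray
    map_idx: np.ndarray  # λ=1 filter MAP per trial
    posterior: np.ndarray  # λ=1 filter posterior per trial
    gain: np.ndarray  # belief-change G from the λ=1 filter


class WaitTimeModel:
    """Wait-time model bound to a trial table (statsmodels-style).

    Parameters
    ----------
    trials
        Trial table (one rat), rows time-ordered within each session.
    model
        One of ``inferential``, ``belief_state``, ``lambda_inferential``,
        ``retrospective``.
    tau_delay, catch_prob
        Task constants; ``catch_prob`` defaults to the empirical catch
        fraction among completed trials.  C = 1 − catch_prob is never fitted.
    hazard_rate
        Block hazard H0 (constant, default 1/40).
    noise_var
        Linear-scale observation variance (s², default 8).
    reward_timescale
        Seconds dividing rewards in the retrospective update (fixed).
    gain_mode
        Gain variant for the retrospective model.
    bounds
        Optional dict parameter-name -> (lower, upper) overriding defaults.
    """

    def __init__(
        self,
        trials: pd.DataFrame,
        model: str = "inferential",
        *,
        tau_delay: float = 2.5,
        catch_prob: float | None = None,
        hazard_rate: float = DEFAULT_HAZARD,
        noise_var: float = 8.0,
        reward_timescale: float = 1.0,
        gain_mode: str = "belief_change",
        init_posterior: str = "mixed",
        update_on_violations: bool = True,
        retrospective_skip_violations: bool = True,
        bounds: dict | None = None,
    ):
        if model not in FIT_MODELS:
            raise ValueError(f"unknown model {model!r}; expected one of {FIT_MODELS}")
        self.model = model
        self.trials = trials
        self.tau_delay = float(tau_delay)
        self.hazard_rate = float(hazard_rate)
        self.noise_var = float(noise_var)
        self.reward_timescale = float(reward_timescale)
        self.gain_mode = gain_mode
        self.init_posterior = init_posterior
        self.update_on_violations = update_on_violations
        self.retrospective_skip_violations = retrospective_skip_violations

        completed = ~trials["is_violation"].astype(bool)
        if catch_prob is None:
            catch_prob = float(trials.loc[completed, "is_catch"].astype(bool).mean())
        if not 0.0 < catch_prob < 1.0:
            raise ValueError("catch_prob must lie strictly in (0, 1)")
        self.catch_prob = catch_prob

        self._data = self._prepare(trials)
        self.nobs = int(self._data.wait_obs.size)
        if self.nobs == 0:
            raise EmptyDataError("no catch-trial wait times to fit")
        self.param_names = _PARAM_NAMES[model]
        self.bounds = self._default_bounds()
        if bounds:
            for name, b in bounds.items():
                self.bounds[self.param_names.index(name)] = tuple(b)

    # ------------------------------------------------------------------
    def _prepare(self, trials: pd.DataFrame) -> _StackedData:
        p0 = (
            np.array([0.0, 1.0, 0.0])
            if self.init_posterior == "mixed"
            else np.full(3, 1.0 / 3.0)
        )
        hazT = np.ascontiguousarray(build_hazard_matrix(self.hazard_rate).T)
        offers_l, viol_l, catch_l, wait_l, starts = [], [], [], [], []
        n = 0
        for _, g in trials.groupby(["rat_id", "session_id"], sort=False):
            starts.append(n)
            offers_l.append(g["reward_offer"].to_numpy(dtype=float))
            viol_l.append(g["is_violation"].to_numpy(dtype=bool))
            catch_l.append(g["is_catch"].to_numpy(dtype=bool))
            wait_l.append(g["wait_time"].to_numpy(dtype=float))
            n += len(g)
        offers = np.concatenate(offers_l)
        viol = np.concatenate(viol_l)
        is_catch = np.concatenate(catch_l)
        wait = np.concatenate(wait_l)
        starts = np.asarray(starts, dtype=np.int64)
        scored = is_catch & np.isfinite(wait) & (wait > 0)
        lik = np.ascontiguousarray(likelihood_matrix(offers))
        upd = np.ones(offers.size, dtype=np.bool_)
        if not self.update_on_violations:
            upd = ~viol
        # λ=1 filter trace (posterior, MAP, gain) is parameter-free: run once
        posts_l, gain_l = [], []
        for i, s0 in enumerate(starts):
            s1 = starts[i + 1] if i + 1 < starts.size else offers.size
            _, p = _filter_loop(lik[s0:s1], hazT, 1.0, p0, upd[s0:s1])
            posts_l.append(p)
            gain_l.append(belief_change_gain(p))
        posts = np.concatenate(posts_l)
        gain = np.concatenate(gain_l)
        self._hazT = hazT
        self._p0 = p0
        self._filter_upd = upd
        return _StackedData(
            offers=offers,
            lik=lik,
            viol=viol,
            starts=starts,
            catch_rows=np.flatnonzero(scored),
            wait_obs=wait[scored],
            map_idx=map_block_indices(posts),
            posterior=posts,
            gain=gain,
        )

    def _default_bounds(self) -> list[tuple[float, float]]:
        kmax = 79.9 / self.tau_delay  # beyond this every offer is clamped
        kb = (1e-2, kmax)
        if self.model == "retrospective":
            return [(1e-2, 80.0 / self.reward_timescale), (1e-3, 1.0), (1e-2, 20.0)]
        b = [kb, kb, kb, (1e-2, 20.0)]
        if self.model == "lambda_inferential":
            b.append((0.0, 1.0))
        return b

    # ------------------------------------------------------------------
    def nll(self, params: np.ndarray) -> float:
        """Total negative log likelihood of the catch-trial wait times."""
        params = np.asarray(params, dtype=float)
        d = self._data
        kappa = self._kappa_scored(params)
        D = float(params[3] if self.model != "retrospective" else params[2])
        kt = kappa * self.tau_delay
        odds = (1.0 - self.catch_prob) / self.catch_prob
        arg = odds * (d.offers[d.catch_rows] - kt) / kt
        pred = np.where(
            arg > 1e-12,
            D * self.tau_delay * np.log(np.maximum(arg, 1e-12)),
            WT_FLOOR,
        )
        pred = np.maximum(pred, WT_FLOOR)
        return float(np.sum(lognormal_nll(d.wait_obs, pred, self.noise_var)))

    def _kappa_full(self, params: np.ndarray) -> np.ndarray:
        """Per-trial κ over the whole (concatenated) trial table."""
        params = np.asarray(params, dtype=float)
        d = self._data
        if self.model == "inferential":
            return params[:3][d.map_idx]
        if self.model == "belief_state":
            return d.posterior @ params[:3]
        if self.model == "lambda_inferential":
            midx = _filter_map_multi(
                d.lik, self._hazT, float(params[4]), self._p0,
                self._filter_upd, d.starts,
            )
            return params[:3][midx]
        # retrospective
        upd = (
            ~d.viol
            if self.retrospective_skip_violations
            else np.ones(d.offers.size, dtype=np.bool_)
        )
        if self.gain_mode == "static":
            G = np.ones(d.offers.size)
        elif self.gain_mode == "belief_change":
            G = d.gain
        else:
            G = np.zeros(d.offers.size)
        return _retro_multi(
            np.ascontiguousarray(d.offers / self.reward_timescale),
            upd,
            np.ascontiguousarray(G, dtype=np.float64),
            float(params[1]),
            float(params[0]),
            self.gain_mode == "abs_rpe",
            1000.0,
            d.starts,
        )

    def _kappa_scored(self, params: np.ndarray) -> np.ndarray:
        """κ at the scored (catch, wait-observed) trials only."""
        d = self._data
        if self.model == "inferential":
            return params[:3][d.map_idx[d.catch_rows]]
        if self.model == "belief_state":
            return d.posterior[d.catch_rows] @ params[:3]
        return self._kappa_full(params)[d.catch_rows]

    # ------------------------------------------------------------------
    def _draw_starts(self, n_starts: int, rng: np.random.Generator) -> np.ndarray:
        """Random starts, log-uniform for scale-like parameters.

        Half the starts for the κ-triple models are sorted
        (κ_low ≤ κ_mixed ≤ κ_high), matching the task's value ordering; the
        likelihood itself never imposes the ordering.
        """
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        llo = np.log(np.maximum(lo, 1e-3))
        lhi = np.log(hi)
        starts = np.exp(llo + rng.random((n_starts, lo.size)) * (lhi - llo))
        if self.model == "lambda_inferential":
            starts[:, 4] = rng.random(n_starts)  # λ uniform on [0, 1]
        if self.model != "retrospective":
            half = n_starts // 2
            starts[:half, :3] = np.sort(starts[:half, :3], axis=1)
        # very large D starts push every prediction off-scale; keep D moderate
        d_col = 2 if self.model == "retrospective" else 3
        starts[:, d_col] = np.minimum(starts[:, d_col], 5.0)
        return np.clip(starts, lo, hi)

    def _polish(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        """Derivative-free polish; the clamp boundary makes the NLL kinked."""
        res = minimize(
            self.nll,
            x,
            method="Nelder-Mead",
            bounds=self.bounds,
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 2000},
        )
        return (res.x, float(res.fun)) if res.fun <= self.nll(x) else (x, self.nll(x))

    def _coordinate_refine(
        self, x: np.ndarray, fx: float, n_grid: int = 60, rounds: int = 3
    ) -> tuple[np.ndarray, float]:
        """1-D log-grid scans per parameter around the incumbent.

        Escapes the flat clamped-prediction plateaus that trap gradient
        steps: a coordinate scan sees the narrow likelihood valley even when
        the local gradient is exactly zero.
        """
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        for _ in range(rounds):
            improved = False
            for j in range(x.size):
                grid = np.exp(
                    np.linspace(np.log(max(lo[j], 1e-3)), np.log(hi[j]), n_grid)
                )
                if self.model == "lambda_inferential" and j == 4:
                    grid = np.linspace(0.0, 1.0, n_grid)
                cand = np.tile(x, (n_grid, 1))
                cand[:, j] = grid
                vals = np.array([self.nll(c) for c in cand])
                b = int(np.argmin(vals))
                if vals[b] < fx - 1e-9:
                    x = cand[b].copy()
                    x, fx = self._polish(x)
                    improved = True
            if not improved:
                break
        return x, fx

    def fit(
        self,
        n_starts: int = 20,
        seed: int = 0,
        x0: np.ndarray | None = None,
        refine: bool = True,
    ) -> "WaitTimeResults":
        """Multi-start bound-constrained MLE; returns the best start.

        Each start runs L-BFGS-B followed by a Nelder-Mead polish; the
        incumbent then gets a coordinate-scan refinement (``refine=False``
        skips it).  ``x0`` replaces the first random start.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        starts = self._draw_starts(n_starts, rng)
        if x0 is not None:
            starts[0] = np.clip(np.asarray(x0, dtype=float), lo, hi)
        best_x, best_f = None, np.inf
        start_nlls = np.full(n_starts, np.nan)
        any_converged = False
        for i, s0 in enumerate(starts):
            res = minimize(
                self.nll,
                s0,
                method="L-BFGS-B",
                bounds=self.bounds,
                options={"ftol": 1e-10, "gtol": 1e-6, "maxiter": 500},
            )
            x, f = self._polish(res.x)
            start_nlls[i] = f
            any_converged = any_converged or res.success
            if f < best_f:
                best_x, best_f = x, f
        if not any_converged and not np.isfinite(start_nlls).any():
            raise FittingError("optimizer failed to converge from every start")
        if refine:
            best_x, best_f = self._coordinate_refine(best_x, best_f)
        k = len(self.param_names)
        bic, aic = information_criteria(best_f, k, self.nobs)
        return WaitTimeResults(
            model=self,
            params=np.asarray(best_x, dtype=float),
            nll=float(best_f),
            start_nlls=start_nlls,
            bic=bic,
            aic=aic,
        )

    # ------------------------------------------------------------------
    def crossval(
        self, folds: int = 5, n_starts: int = 20, seed: int = 0
    ) -> pd.DataFrame:
        """Session-blocked k-fold cross-validation.

        Sessions are partitioned into ``folds`` contiguous groups (respecting
        the sequential state within sessions); each fold is held out once,
        the model refit on the rest, and the held-out total and per-trial
        test NLL reported.
        """
        keys = list(
            self.trials.groupby(["rat_id", "session_id"], sort=False).groups
        )
        if folds < 2:
            raise ValueError("cv_folds must be at least 2")
        if folds > len(keys):
            raise ValueError(
                f"cannot make {folds} session folds from {len(keys)} sessions"
            )
        key_col = list(zip(self.trials["rat_id"], self.trials["session_id"]))
        fold_keys = np.array_split(np.arange(len(keys)), folds)
        rows = []
        for f, idx in enumerate(fold_keys):
            test_keys = {keys[i] for i in idx}
            in_test = np.array([k in test_keys for k in key_col])
            train = self.trials.loc[~in_test]
            test = self.trials.loc[in_test]
            kw = dict(
                tau_delay=self.tau_delay,
                catch_prob=self.catch_prob,
                hazard_rate=self.hazard_rate,
                noise_var=self.noise_var,
                reward_timescale=self.reward_timescale,
                gain_mode=self.gain_mode,
                init_posterior=self.init_posterior,
                update_on_violations=self.update_on_violations,
                retrospective_skip_violations=self.retrospective_skip_violations,
            )
            m_train = WaitTimeModel(train, self.model, **kw)
            res = m_train.fit(n_starts=n_starts, seed=seed + f)
            m_test = WaitTimeModel(test, self.model, **kw)
            test_nll = m_test.nll(res.params)
            rows.append(
                {
                    "fold": f,
                    "n_train": m_train.nobs,
                    "n_test": m_test.nobs,
                    "train_nll_per_trial": res.nll / m_train.nobs,
                    "test_nll": test_nll,
                    "test_nll_per_trial": test_nll / m_test.nobs,
                }
            )
        return pd.DataFrame(rows)


class WaitTimeResults:
    """Fitted wait-time model: estimates, information criteria, diagnostics."""

    def __init__(self, model, params, nll, start_nlls, bic, aic):
        self.model = model
        self.params = params
        self.nll = nll
        self.start_nlls = start_nlls
        self.bic = bic
        self.aic = aic
        self.nobs = model.nobs
        self.k = len(model.param_names)
        self._bse = None

    @property
    def params_dict(self) -> dict:
        return dict(zip(self.model.param_names, self.params))

    @property
    def bse(self) -> np.ndarray:
        """Standard errors from the inverse finite-difference Hessian.

        NaN where the Hessian is singular or the estimate sits on a bound.
        """
        if self._bse is None:
            self._bse = self._hessian_se()
        return self._bse

    def _hessian_se(self) -> np.ndarray:
        x = self.params
        n = x.size
        h = np.maximum(1e-4, 1e-4 * np.abs(x))
        H = np.empty((n, n))
        f0 = self.model.nll(x)

        def f(v):
            return self.model.nll(v)

        for i in range(n):
            for j in range(i, n):
                ei = np.zeros(n)
                ej = np.zeros(n)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(x + ei + ej) - f(x + ei) - f(x + ej) + f0
                    ) / (h[i] * h[j])
        try:
            cov = np.linalg.inv(H)
            d = np.diag(cov)
            return np.where(d > 0, np.sqrt(np.abs(d)), np.nan)
        except np.linalg.LinAlgError:
            return np.full(n, np.nan)

    def kappa_trace(self) -> np.ndarray:
        """Fitted per-trial κ over the full trial table (session order)."""
        return self.model._kappa_full(self.params)

    def summary(self) -> str:
        lines = [
            "Wait-time model results",
            "=" * 54,
            f"model:           {self.model.model}",
            f"n wait times:    {self.nobs}",
            f"nLL:             {self.nll:.4f}",
            f"BIC:             {self.bic:.4f}",
            f"AIC:             {self.aic:.4f}",
            f"tau (fixed):     {self.model.tau_delay:g} s",
            f"C (fixed):       {1 - self.model.catch_prob:g}",
            "-" * 54,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}",
        ]
        bse = self.bse
        for name, val, se in zip(self.model.param_names, self.params, bse):
            se_s = f"{se:12.4f}" if np.isfinite(se) else "         ---"
            lines.append(f"{name:<14}{val:12.4f}{se_s}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def __repr__(self):  # pragma: no cover
        return (
            f"<WaitTimeResults {self.model.model}: nll={self.nll:.2f} "
            f"bic={self.bic:.2f} n={self.nobs}>"
        )


def compare_models(fit_a: WaitTimeResults, fit_b: WaitTimeResults) -> float:
    """ΔBIC = BIC(a) − BIC(b); negative favors model a.

    Both fits must score the same observations.
    """
    if fit_a.nobs != fit_b.nobs:
        raise ValueError(
            f"fits score different data: n={fit_a.nobs} vs n={fit_b.nobs}"
        )
    return float(fit_a.bic - fit_b.bic)


# ----------------------------------------------------------------------
# parameter-recovery harness
# ----------------------------------------------------------------------

def recover_parameters(
    model: str,
    gen_params: dict,
    n_trials: int = 5000,
    n_starts: int = 20,
    seed: int = 0,
    config=None,
    agent_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Simulate from known parameters, refit, and tabulate the recovery.

    ``gen_params`` are keyword arguments of :func:`inferential_agent` /
    :func:`retrospective_agent`; only those with a fitted counterpart appear
    in the report.  Returns a DataFrame with columns ``parameter``,
    ``generative``, ``recovered``, ``rel_error``.
    """
    from .agents import inferential_agent, retrospective_agent, simulate_trials
    from .task import SessionConfig

    if config is None:
        config = SessionConfig()
    agent_kwargs = dict(agent_kwargs or {})
    if model == "retrospective":
        agent = retrospective_agent(**gen_params, **agent_kwargs)
        ts = agent.value_params.reward_timescale
    else:
        agent = inferential_agent(**gen_params, **agent_kwargs)
        ts = 1.0
    trials = simulate_trials(agent, n_trials, config=config, seed=seed)
    wm = WaitTimeModel(
        trials,
        model,
        tau_delay=config.mean_delay,
        catch_prob=config.catch_prob,
        reward_timescale=ts,
        gain_mode=agent.value_params.gain_mode,
    )
    res = wm.fit(n_starts=n_starts, seed=seed + 1)
    gen_full = {
        "kappa_low": agent.value_params.kappa_low,
        "kappa_mixed": agent.value_params.kappa_mixed,
        "kappa_high": agent.value_params.kappa_high,
        "kappa_init": agent.value_params.kappa_init,
        "alpha0": agent.value_params.alpha0,
        "lambda_mix": agent.value_params.lambda_mix,
        "D_wt": agent.wait_params.D_wt,
    }
    rows = []
    for name, rec in res.params_dict.items():
        g = gen_full[name]
        rows.append(
            {
                "parameter": name,
                "generative": g,
                "recovered": rec,
                "rel_error": (rec - g) / g if g != 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def recovery_grid(
    model: str,
    param: str,
    values,
    n_trials: int = 5000,
    n_starts: int = 20,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Recovery across a grid of one generative parameter.

    Returns per-value generative/recovered pairs plus the Spearman rank
    correlation (same value in every row).
    """
    from scipy.stats import spearmanr

    rows = []
    for i, v in enumerate(values):
        rep = recover_parameters(
            model, {param: v}, n_trials=n_trials, n_starts=n_starts,
            seed=seed + 1000 * i, **kwargs,
        )
        rec = rep.set_index("parameter").loc[param, "recovered"]
        rows.append({"generative": v, "recovered": rec})
    df = pd.DataFrame(rows)
    if len(df) > 2 and df["generative"].nunique() > 2:
        rho = spearmanr(df["generative"], df["recovered"]).statistic
    else:
        rho = np.nan if len(df) < 2 else float(
            np.sign(np.diff(df["recovered"]).prod())
        )
    df["rank_corr"] = rho
    return df


def fit_ti_scale(trial_initiation: np.ndarray, kappa: np.ndarray) -> float:
    """Least-squares D for TI = D/κ (synthetic recovery harness only).

    The trial-initiation models are never fit to wait-time-style data; this
    exists to verify that noiseless TI data inverts exactly.
    """
    ti = np.asarray(trial_initiation, dtype=float)
    x = 1.0 / np.asarray(kappa, dtype=float)
    return float(np.sum(ti * x) / np.sum(x * x))
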