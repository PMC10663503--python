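"""Wait-time and trial-initiation-time models with log-normal noise.

Waiting at the reward port is treated as foraging in a depleting patch: with
an exponential delay distribution (time constant τ) and reward probability C,
the point at which the trial's value falls below the opportunity cost κ gives
the predicted wait time

    WT = D τ ln( C/(1−C) · (R − κτ)/(κτ) )

with R the offered volume and D a free scale.  WT increases with the offer
and with reward probability and decreases with the richness of the
environment.  The expression is undefined for R ≤ κτ (the trial is never
worth waiting for); predictions there, and any prediction below it, are
floored at ``WT_FLOOR`` seconds.

Trial initiation follows the reward-rate-optimal latency TI = D/κ: the richer
the environment, the faster the animal starts the next trial.

Observed times are modelled as log-normal around the predicted time with a
*constant variance on the linear scale* (8 s² for wait times, 4 s² for
initiation times), obtained by moment matching:

    σ² = ln(1 + v/m²),   μ = ln m − σ²/2

so that the log-normal's mean is the model prediction m and its variance is v.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: smallest admissible predicted time, seconds (Eq-domain clamp)
WT_FLOOR = 1e-3

#: smallest admissible log argument before clamping
_ARG_FLOOR = 1e-12


@dataclass
class WaitTimeParams:
    """Wait-time model parameters.

    D_wt: dimensionless scale; tau_delay: exponential-delay time constant
    (s); C: probability of reward (1 − catch probability); noise_var_wt:
    observation variance (s²).
    """

    D_wt: float = 1.0
    tau_delay: float = 2.5
    C: float = 0.8
    noise_var_wt: float = 8.0

    def __post_init__(self):
        if self.D_wt <= 0 or self.tau_delay <= 0 or self.noise_var_wt <= 0:
            raise ValueError("D_wt, tau_delay and noise_var_wt must be positive")
        if not 0.0 < self.C < 1.0:
            raise ValueError("C must lie strictly between 0 and 1")


@dataclass
class TIParams:
    """Trial-initiation model parameters (TI = D_ti / κ)."""

    D_ti: float = 25.0
    noise_var_ti: float = 4.0

    def __post_init__(self):
        if self.D_ti <= 0 or self.noise_var_ti <= 0:
            raise ValueError("D_ti and noise_var_ti must be positive")


def predict_wait_time(R, kappa, params: WaitTimeParams):
    """Predicted wait time (s); scalar or elementwise over arrays.

    Predictions whose log argument is non-positive (R ≤ κτ) or that fall
    below ``WT_FLOOR`` are clamped to ``WT_FLOOR``.
    """
    R = np.asarray(R, dtype=float)
    kappa = np.asarray(kappa, dtype=float)
    if np.any(R <= 0) or np.any(kappa <= 0):
        raise ValueError("R and kappa must be positive")
    kt = kappa * params.tau_delay
    odds = params.C / (1.0 - params.C)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg = odds * (R - kt) / kt
        wt = np.where(
            arg > _ARG_FLOOR,
            params.D_wt * params.tau_delay * np.log(np.maximum(arg, _ARG_FLOOR)),
            WT_FLOOR,
        )
    out = np.maximum(wt, WT_FLOOR)
    return float(out) if out.ndim == 0 else out


def predict_trial_initiation(kappa, params: TIParams):
    """Predicted trial-initiation time TI = D_ti / κ (s)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    out = params.D_ti / kappa
    return float(out) if out.ndim == 0 else out


def lognormal_params(mean, variance):
    """(μ, σ²) of the log-normal with the given linear-scale mean and variance."""
    m = np.asarray(mean, dtype=float)
    v = np.asarray(variance, dtype=float)
    if np.any(m <= 0) or np.any(v <= 0):
        raise ValueError("mean and variance must be positive")
    sigma2 = np.log1p(v / (m * m))
    mu = np.log(m) - 0.5 * sigma2
    return mu, sigma2


def lognormal_nll(observed, predicted_mean, variance):
    """Negative log density of the moment-matched log-normal.

    Scalar inputs give a scalar; array inputs give the elementwise NLL (sum
    it for a dataset likelihood).
    """
    x = np.asarray(observed, dtype=float)
    if np.any(x <= 0):
        raise ValueError("observed times must be positive")
    mu, sigma2 = lognormal_params(predicted_mean, variance)
    z = np.log(x) - mu
    nll = 0.5 * np.log(2.0 * np.pi * sigma2) + np.log(x) + z * z / (2.0 * sigma2)
    return float(nll) if nll.ndim == 0 else nll


def sample_lognormal(mean, variance, rng: np.random.Generator):
    """Draw observation(s) from the moment-matched log-normal noise model."""
    mu, sigma2 = lognormal_params(mean, variance)
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2))
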