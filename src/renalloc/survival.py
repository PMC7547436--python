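"""Weibull proportional-hazards fitting and probability conversions.

Transition probabilities for the cohort model come in two flavours:

* time-dependent, from a Weibull proportional-hazards regression with a
  recipient-age covariate (transplant, graft failure, post-transplant
  death), converted cycle by cycle via :func:`annual_transition_probability`;
* time-constant, from a cumulative incidence over a follow-up window,
  converted through a rate to an annual probability via
  :func:`cumulative_incidence_to_annual_probability`.
"""

from __future__ import annotations

import numpy as np
from statsmodels.base.model import GenericLikelihoodModel

from .parameters import CumulativeIncidence, WeibullHazardParams

__all__ = [
    "fit_weibull_ph",
    "annual_transition_probability",
    "cumulative_incidence_to_annual_probability",
    "empirical_cumulative_incidence",
    "ConvergenceError",
]


class ConvergenceError(RuntimeError):
    """Raised when the Weibull likelihood cannot be maximised reliably."""


def annual_transition_probability(
    params: WeibullHazardParams, age: float, cycle_t: int | np.ndarray
) -> float | np.ndarray:
    """Conditional probability of the event during cycle ``cycle_t``.

    With cumulative hazard ``H(t) = lam * exp(beta_age*age) * t**gamma`` the
    probability of the event in year ``t`` given event-free survival to
    ``t-1`` is ``1 - S(t)/S(t-1) = 1 - exp(H(t-1) - H(t))``, which lies in
    [0, 1] for any positive ``lam``, ``gamma``.
    """
    t = np.asarray(cycle_t, dtype=float)
    if np.any(t < 1):
        raise ValueError("cycle_t must be >= 1")
    scale = params.lam * np.exp(params.beta_age * age)
    out = -np.expm1(scale * ((t - 1.0) ** params.gamma - t**params.gamma))
    if np.isscalar(cycle_t):
        return float(out)
    return out


def cumulative_incidence_to_annual_probability(ci: CumulativeIncidence) -> float:
    """Convert a cumulative incidence over ``duration_T`` years to an annual
    probability through the constant-rate chain
    ``r = -ln(1-p)/T``;  ``p_annual = 1 - exp(-r)``.
    """
    rate = -np.log1p(-ci.p) / ci.duration_T
    return float(-np.expm1(-rate))


def empirical_cumulative_incidence(times, events, duration_T: float) -> CumulativeIncidence:
    """Event proportion by ``duration_T`` with a binomial standard error.

    ``times`` are observed follow-up times, ``events`` the event indicators.
    Subjects censored before ``duration_T`` are counted in the denominator
    (simple proportion, matching a registry-count estimate on a cohort with
    near-complete follow-up over the window).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty input")
    if duration_T <= 0:
        raise ValueError("duration_T must be > 0")
    n = times.size
    k = int(np.sum(events & (times <= duration_T)))
    p = k / n
    sem = float(np.sqrt(p * (1.0 - p) / n))
    return CumulativeIncidence(p=p, duration_T=duration_T, sem=sem)


class _WeibullPHLikelihood(GenericLikelihoodModel):
    """Weibull PH log-likelihood in (log lam, log gamma, beta) coordinates.

    Per-subject contribution with right censoring:
    ``delta*(log lam + log gamma + (gamma-1) log t + beta*x) - lam*exp(beta*x)*t**gamma``.
    """

    def __init__(self, times, events, ages, **kwargs):
        endog = np.column_stack([times, events])
        super().__init__(endog=endog, exog=np.asarray(ages, float), **kwargs)
        self._times = np.asarray(times, float)
        self._events = np.asarray(events, float)
        self._ages = np.asarray(ages, float)
        # GenericLikelihoodModel infers names from exog; set ours explicitly
        self.data.xnames = ["log_lam", "log_gamma", "beta_age"]

    def nloglikeobs(self, params):
        log_lam, log_gamma, beta = params
        lam, gamma = np.exp(log_lam), np.exp(log_gamma)
        t, d, x = self._times, self._events, self._ages
        log_h = log_lam + log_gamma + (gamma - 1.0) * np.log(t) + beta * x
        cum_h = lam * np.exp(beta * x) * t**gamma
        return -(d * log_h - cum_h)


def fit_weibull_ph(times, events, ages) -> WeibullHazardParams:
    """Maximum-likelihood Weibull proportional-hazards fit with an age covariate.

    Hazard ``h(t | age) = lam * gamma * t**(gamma-1) * exp(beta_age * age)``.
    The likelihood is maximised in ``(log lam, log gamma, beta_age)``;
    standard errors on the natural scale follow by the delta method from the
    observed information.

    Raises
    ------
    ValueError
        If no events are observed, any time is non-positive, or the age
        covariate is constant (``beta_age`` unidentifiable).
    ConvergenceError
        If the optimiser fails, with the optimiser diagnostics attached.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    ages = np.asarray(ages, dtype=float)
    if not (times.shape == events.shape == ages.shape):
        raise ValueError("times, events and ages must have equal shapes")
    if np.any(times <= 0):
        raise ValueError("all times must be > 0")
    if not np.any(events):
        raise ValueError("at least one event is required (all observations censored)")
    if np.ptp(ages) == 0.0:
        raise ValueError(
            "age covariate is constant: beta_age is unidentifiable "
            f"(all ages equal {ages[0]:g})"
        )

    # moment-style start: exponential rate at the mean age, gamma = 1
    rate0 = events.sum() / np.sum(times)
    start = np.array([np.log(rate0) - 0.0, 0.0, 0.0])
    model = _WeibullPHLikelihood(times, events.astype(float), ages)
    import warnings

    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        # statsmodels complains about df bookkeeping for custom likelihoods
        warnings.filterwarnings("ignore", message="df_model", category=UserWarning)
        warnings.filterwarnings("ignore", message="df_resid", category=UserWarning)
        res = model.fit(start_params=start, method="bfgs", maxiter=500, disp=0)
    retvals = getattr(res, "mle_retvals", {}) or {}
    if not retvals.get("converged", True):
        raise ConvergenceError(f"Weibull PH fit did not converge: {retvals}")
    log_lam, log_gamma, beta = res.params
    se_log_lam, se_log_gamma, se_beta = res.bse
    if not np.all(np.isfinite(res.params)) or not np.all(np.isfinite(res.bse)):
        raise ConvergenceError(
            f"non-finite estimates or standard errors: params={res.params}, bse={res.bse}"
        )
    lam, gamma = float(np.exp(log_lam)), float(np.exp(log_gamma))
    return WeibullHazardParams(
        lam=lam,
        gamma=gamma,
        beta_age=float(beta),
        sem_lam=lam * float(se_log_lam),  # delta method: d(lam)/d(log lam) = lam
        sem_gamma=gamma * float(se_log_gamma),
        sem_beta=float(se_beta),
    )
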