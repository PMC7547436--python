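"""Four-state Markov cohort model with transplant tunnel states.

States: waitlisted (on dialysis), transplanted (expanded into one tunnel
state per year since transplant, because graft failure and post-transplant
mortality depend on time since transplant, not model time), post
graft-failure dialysis (permanent; no re-listing), and death (absorbing).

The whole cohort is listed at time zero, so the waitlist transplant
probability is evaluated at model time; tunnel transitions are evaluated at
time since transplant.  Competing exits from a state are independently
computed annual probabilities; should their sum exceed one they are
proportionally rescaled (a warning is emitted — with realistic parameters
this never triggers).

Payoffs are state payoffs per cycle, taken on the end-of-cycle occupancy
(or the average of start and end when ``half_cycle_correction`` is on) and
discounted per :meth:`renalloc.parameters.ModelConfig.discount_factor`.
Death carries zero cost and zero utility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import AllocationScenario, ModelConfig

__all__ = [
    "CohortTrace",
    "EconomicResult",
    "cycle_transition_probabilities",
    "run_cohort",
    "accumulate_outcomes",
    "evaluate_scenario",
    "batch_outcomes",
]


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle state occupancy.  Row 0 is the initial distribution.

    ``tunnel[c, k-1]`` is the occupancy of the k-th year-since-transplant
    tunnel after cycle ``c``; ``waitlist``, ``post_gf`` and ``dead`` are
    vectors of length ``horizon + 1``.
    """

    waitlist: np.ndarray
    tunnel: np.ndarray
    post_gf: np.ndarray
    dead: np.ndarray

    @property
    def transplanted(self) -> np.ndarray:
        """Total occupancy across all transplant tunnels, per cycle."""
        return self.tunnel.sum(axis=1)

    def occupancy_totals(self) -> np.ndarray:
        return self.waitlist + self.transplanted + self.post_gf + self.dead

    def to_frame(self) -> pd.DataFrame:
        n_cycles, horizon = self.tunnel.shape
        data = {"cycle": np.arange(n_cycles), "waitlist": self.waitlist}
        for k in range(horizon):
            data[f"tx_year_{k + 1}"] = self.tunnel[:, k]
        data["post_graft_failure"] = self.post_gf
        data["dead"] = self.dead
        return pd.DataFrame(data)


@dataclass(frozen=True)
class EconomicResult:
    """Discounted totals for a whole cohort over the full horizon."""

    total_cost: float
    total_qaly: float


def _rescale_competing(probs: list[np.ndarray | float], context: str):
    """Proportionally rescale competing exit probabilities whose sum exceeds 1."""
    total = sum(probs)
    if np.any(np.asarray(total) > 1.0):
        warnings.warn(
            f"competing exit probabilities exceed 1 in {context}; rescaling proportionally",
            RuntimeWarning,
            stacklevel=3,
        )
        excess = np.maximum(total, 1.0)
        probs = [p / excess for p in probs]
    return probs


def _weibull_cycle_prob(lam, gamma, beta, age, t):
    """Vectorised conditional cycle probability; ``t`` may be an array."""
    scale = lam * np.exp(beta * age)
    return -np.expm1(scale * ((t - 1.0) ** gamma - t**gamma))


def cycle_transition_probabilities(
    scenario: AllocationScenario,
    config: ModelConfig,
    model_cycle: int,
    tunnel_index: int,
) -> dict[str, dict[str, float]]:
    """Outgoing transition probabilities for every state at one cycle.

    Waitlist exits use the transplant hazard at ``model_cycle`` (time since
    listing) and the fixed waitlist mortality; tunnel exits use the graft
    failure and post-transplant death hazards at ``tunnel_index`` (time
    since transplant); post-graft-failure dialysis exits with the fixed
    annual mortality.  Every state's row sums to exactly 1.
    """
    if not 1 <= model_cycle <= config.horizon:
        raise ValueError(f"model_cycle must be in [1, {config.horizon}], got {model_cycle}")
    if not 1 <= tunnel_index <= model_cycle:
        raise ValueError(f"tunnel_index must be in [1, {model_cycle}], got {tunnel_index}")

    wp = scenario.p_transplant
    p_tx = _weibull_cycle_prob(wp.lam, wp.gamma, wp.beta_age, config.age, float(model_cycle))
    p_dw = scenario.p_death_waitlist.p
    p_tx, p_dw = _rescale_competing([p_tx, p_dw], "waitlist")

    gp, dp = scenario.p_graft_failure, scenario.p_death_post_tx
    p_gf = _weibull_cycle_prob(gp.lam, gp.gamma, gp.beta_age, config.age, float(tunnel_index))
    p_dt = _weibull_cycle_prob(dp.lam, dp.gamma, dp.beta_age, config.age, float(tunnel_index))
    p_gf, p_dt = _rescale_competing([p_gf, p_dt], "transplant tunnel")

    p_dgf = scenario.p_death_post_gf.p
    return {
        "waitlist": {
            "transplant": float(p_tx),
            "death": float(p_dw),
            "stay": float(1.0 - p_tx - p_dw),
        },
        "transplant": {
            "graft_failure": float(p_gf),
            "death": float(p_dt),
            "stay": float(1.0 - p_gf - p_dt),
        },
        "post_graft_failure": {"death": float(p_dgf), "stay": float(1.0 - p_dgf)},
        "death": {"stay": 1.0},
    }


def _tunnel_probability_grid(scenario: AllocationScenario, config: ModelConfig):
    """(p_graft_failure, p_death) arrays over tunnel years 1..horizon."""
    ks = np.arange(1, config.horizon + 1, dtype=float)
    gp, dp = scenario.p_graft_failure, scenario.p_death_post_tx
    p_gf = _weibull_cycle_prob(gp.lam, gp.gamma, gp.beta_age, config.age, ks)
    p_dt = _weibull_cycle_prob(dp.lam, dp.gamma, dp.beta_age, config.age, ks)
    p_gf, p_dt = _rescale_competing([p_gf, p_dt], "transplant tunnel")
    return p_gf, p_dt


def run_cohort(scenario: AllocationScenario, config: ModelConfig) -> CohortTrace:
    """Propagate the cohort cycle by cycle; whole cohort starts waitlisted.

    New transplants enter tunnel 1; tunnel ``k`` advances to ``k+1``; graft
    failures move to post-graft-failure dialysis permanently; death is
    absorbing.  The trace conserves cohort mass at every cycle.
    """
    H = config.horizon
    waitlist = np.zeros(H + 1)
    tunnel = np.zeros((H + 1, H))
    post_gf = np.zeros(H + 1)
    dead = np.zeros(H + 1)
    waitlist[0] = config.cohort_size

    p_gf, p_dt = _tunnel_probability_grid(scenario, config)
    wp = scenario.p_transplant
    p_dw = scenario.p_death_waitlist.p
    p_dgf = scenario.p_death_post_gf.p

    for t in range(1, H + 1):
        p_tx = _weibull_cycle_prob(wp.lam, wp.gamma, wp.beta_age, config.age, float(t))
        p_tx, p_dw_t = _rescale_competing([p_tx, p_dw], "waitlist")
        wl = waitlist[t - 1]
        tun = tunnel[t - 1]

        new_tunnel = np.zeros(H)
        new_tunnel[0] = wl * p_tx
        surviving = tun * (1.0 - p_gf - p_dt)
        new_tunnel[1:] += surviving[:-1]
        # occupants of the final tunnel who neither fail nor die stay there
        new_tunnel[-1] += surviving[-1]

        waitlist[t] = wl * (1.0 - p_tx - p_dw_t)
        post_gf[t] = post_gf[t - 1] * (1.0 - p_dgf) + np.sum(tun * p_gf)
        dead[t] = dead[t - 1] + wl * p_dw_t + np.sum(tun * p_dt) + post_gf[t - 1] * p_dgf
        tunnel[t] = new_tunnel

    return CohortTrace(waitlist=waitlist, tunnel=tunnel, post_gf=post_gf, dead=dead)


def accumulate_outcomes(
    trace: CohortTrace, scenario: AllocationScenario, config: ModelConfig
) -> EconomicResult:
    """Discounted cost and QALY totals from a cohort trace.

    Per cycle: waitlist and post-graft-failure occupancy accrue the dialysis
    cost and dialysis utility; tunnel-1 occupancy accrues the first-year
    transplant cost (plus the annual maintenance cost when
    ``config.first_year_includes_maintenance``); later tunnels accrue the
    maintenance cost and all tunnels the transplant utility.
    """
    totals = trace.occupancy_totals()
    if not np.allclose(totals, totals[0], rtol=1e-9):
        raise ValueError("trace does not conserve cohort mass")

    cost_year1 = scenario.cost_tx_year1
    if config.first_year_includes_maintenance:
        cost_year1 = cost_year1 + scenario.cost_tx_subsequent

    def payoffs(idx: int) -> tuple[float, float]:
        dialysis_occ = trace.waitlist[idx] + trace.post_gf[idx]
        tun = trace.tunnel[idx]
        cost = (
            dialysis_occ * scenario.cost_dialysis
            + tun[0] * cost_year1
            + tun[1:].sum() * scenario.cost_tx_subsequent
        )
        qaly = dialysis_occ * scenario.utility_dialysis + tun.sum() * scenario.utility_transplant
        return cost, qaly

    total_cost = 0.0
    total_qaly = 0.0
    for t in range(1, config.horizon + 1):
        c_end, q_end = payoffs(t)
        if config.half_cycle_correction:
            c_start, q_start = payoffs(t - 1)
            c, q = 0.5 * (c_start + c_end), 0.5 * (q_start + q_end)
        else:
            c, q = c_end, q_end
        df = config.discount_factor(t)
        total_cost += df * c
        total_qaly += df * q
    return EconomicResult(total_cost=float(total_cost), total_qaly=float(total_qaly))


def evaluate_scenario(scenario: AllocationScenario, config: ModelConfig) -> EconomicResult:
    """Convenience: run the cohort and accumulate outcomes in one call."""
    return accumulate_outcomes(run_cohort(scenario, config), scenario, config)


def batch_outcomes(params: dict[str, np.ndarray], config: ModelConfig):
    """Vectorised cohort evaluation over parameter draws.

    ``params`` maps parameter names to equal-length 1-D arrays:
    ``lam_tx, gamma_tx, beta_tx, lam_gf, gamma_gf, beta_gf, lam_dtx,
    gamma_dtx, beta_dtx, p_death_waitlist, p_death_post_gf, cost_tx_year1,
    cost_tx_subsequent, cost_dialysis, utility_transplant, utility_dialysis``.

    Returns ``(total_cost, total_qaly)`` arrays.  Matches a loop of
    :func:`evaluate_scenario` over the draws to machine precision (tested),
    and exists so the 20,000-iteration probabilistic sensitivity analysis
    runs in seconds.
    """
    H = config.horizon
    age = config.age
    I = len(params["p_death_waitlist"])
    get = {k: np.asarray(v, dtype=float) for k, v in params.items()}

    ks = np.arange(1, H + 1, dtype=float)[None, :]
    p_gf = -np.expm1(
        get["lam_gf"][:, None]
        * np.exp(get["beta_gf"][:, None] * age)
        * ((ks - 1.0) ** get["gamma_gf"][:, None] - ks ** get["gamma_gf"][:, None])
    )
    p_dt = -np.expm1(
        get["lam_dtx"][:, None]
        * np.exp(get["beta_dtx"][:, None] * age)
        * ((ks - 1.0) ** get["gamma_dtx"][:, None] - ks ** get["gamma_dtx"][:, None])
    )
    excess = np.maximum(p_gf + p_dt, 1.0)
    p_gf, p_dt = p_gf / excess, p_dt / excess

    p_dw = get["p_death_waitlist"]
    p_dgf = get["p_death_post_gf"]
    cost_year1 = get["cost_tx_year1"]
    if config.first_year_includes_maintenance:
        cost_year1 = cost_year1 + get["cost_tx_subsequent"]

    waitlist = np.full(I, float(config.cohort_size))
    tunnel = np.zeros((I, H))
    post_gf = np.zeros(I)
    total_cost = np.zeros(I)
    total_qaly = np.zeros(I)

    def payoffs(wl, tun, gf):
        dialysis_occ = wl + gf
        cost = (
            dialysis_occ * get["cost_dialysis"]
            + tun[:, 0] * cost_year1
            + tun[:, 1:].sum(axis=1) * get["cost_tx_subsequent"]
        )
        qaly = dialysis_occ * get["utility_dialysis"] + tun.sum(axis=1) * get[
            "utility_transplant"
        ]
        return cost, qaly

    for t in range(1, H + 1):
        c_start, q_start = payoffs(waitlist, tunnel, post_gf) if config.half_cycle_correction else (None, None)
        p_tx = -np.expm1(
            get["lam_tx"]
            * np.exp(get["beta_tx"] * age)
            * ((t - 1.0) ** get["gamma_tx"] - float(t) ** get["gamma_tx"])
        )
        excess_wl = np.maximum(p_tx + p_dw, 1.0)
        p_tx_t, p_dw_t = p_tx / excess_wl, p_dw / excess_wl

        surviving = tunnel * (1.0 - p_gf - p_dt)
        new_tunnel = np.zeros_like(tunnel)
        new_tunnel[:, 0] = waitlist * p_tx_t
        new_tunnel[:, 1:] += surviving[:, :-1]
        new_tunnel[:, -1] += surviving[:, -1]
        post_gf = post_gf * (1.0 - p_dgf) + np.sum(tunnel * p_gf, axis=1)
        waitlist = waitlist * (1.0 - p_tx_t - p_dw_t)
        tunnel = new_tunnel

        c_end, q_end = payoffs(waitlist, tunnel, post_gf)
        if config.half_cycle_correction:
            c, q = 0.5 * (c_start + c_end), 0.5 * (q_start + q_end)
        else:
            c, q = c_end, q_end
        df = config.discount_factor(t)
        total_cost += df * c
        total_qaly += df * q
    return total_cost, total_qaly


def scenario_param_arrays(scenario: AllocationScenario, n: int = 1) -> dict[str, np.ndarray]:
    """Expand a scenario into the parameter-array layout of :func:`batch_outcomes`."""
    vals = {
        "lam_tx": scenario.p_transplant.lam,
        "gamma_tx": scenario.p_transplant.gamma,
        "beta_tx": scenario.p_transplant.beta_age,
        "lam_gf": scenario.p_graft_failure.lam,
        "gamma_gf": scenario.p_graft_failure.gamma,
        "beta_gf": scenario.p_graft_failure.beta_age,
        "lam_dtx": scenario.p_death_post_tx.lam,
        "gamma_dtx": scenario.p_death_post_tx.gamma,
        "beta_dtx": scenario.p_death_post_tx.beta_age,
        "p_death_waitlist": scenario.p_death_waitlist.p,
        "p_death_post_gf": scenario.p_death_post_gf.p,
        "cost_tx_year1": scenario.cost_tx_year1,
        "cost_tx_subsequent": scenario.cost_tx_subsequent,
        "cost_dialysis": scenario.cost_dialysis,
        "utility_transplant": scenario.utility_transplant,
        "utility_dialysis": scenario.utility_dialysis,
    }
    return {k: np.full(n, v, dtype=float) for k, v in vals.items()}
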