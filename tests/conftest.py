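"""Shared fixtures and the individual-level microsimulation oracle."""

from __future__ import annotations

import numpy as np
import pytest

from renalloc import (
    AllocationScenario,
    FixedAnnualProbability,
    ModelConfig,
    WeibullHazardParams,
    default_scenarios,
)


@pytest.fixture(scope="session")
def scenarios() -> dict[str, AllocationScenario]:
    return default_scenarios()


@pytest.fixture()
def base_config() -> ModelConfig:
    return ModelConfig()


def make_scenario(
    name="test",
    lam_tx=0.0,
    gamma_tx=1.0,
    beta_tx=0.0,
    lam_gf=0.0,
    gamma_gf=1.0,
    beta_gf=0.0,
    lam_dtx=0.0,
    gamma_dtx=1.0,
    beta_dtx=0.0,
    p_dw=0.0,
    p_dgf=0.0,
    **kwargs,
) -> AllocationScenario:
    """Scenario with all hazards off unless specified."""
    return AllocationScenario(
        name=name,
        p_transplant=WeibullHazardParams(lam_tx, gamma_tx, beta_tx),
        p_graft_failure=WeibullHazardParams(lam_gf, gamma_gf, beta_gf),
        p_death_post_tx=WeibullHazardParams(lam_dtx, gamma_dtx, beta_dtx),
        p_death_waitlist=FixedAnnualProbability(p_dw),
        p_death_post_gf=FixedAnnualProbability(p_dgf),
        **kwargs,
    )


def microsimulate(scenario: AllocationScenario, config: ModelConfig, n: int, seed: int):
    """Individual-level Monte-Carlo oracle for the cohort engine.

    Simulates ``n`` patients through the same annual transition
    probabilities the cohort model uses (independent of the cohort-engine
    code path) and returns per-cycle occupancy *fractions* for the four
    aggregated states: waitlist, transplanted (any tunnel), post graft
    failure, dead.  Rows 0..horizon.
    """
    from renalloc.survival import annual_transition_probability

    rng = np.random.default_rng(seed)
    H = config.horizon
    age = config.age
    WAIT, TX, GF, DEAD = 0, 1, 2, 3
    state = np.zeros(n, dtype=np.int8)
    tx_year = np.zeros(n, dtype=np.int32)  # years since transplant (tunnel index)
    frac = np.zeros((H + 1, 4))
    frac[0] = [1.0, 0.0, 0.0, 0.0]

    p_dw = scenario.p_death_waitlist.p
    p_dgf = scenario.p_death_post_gf.p
    for t in range(1, H + 1):
        u = rng.random(n)
        new_state = state.copy()
        new_tx_year = tx_year.copy()

        on_wait = state == WAIT
        p_tx = annual_transition_probability(scenario.p_transplant, age, t)
        total = p_tx + p_dw
        scale = 1.0 / total if total > 1 else 1.0
        new_state[on_wait & (u < p_tx * scale)] = TX
        new_tx_year[on_wait & (u < p_tx * scale)] = 1
        new_state[on_wait & (u >= p_tx * scale) & (u < (p_tx + p_dw) * scale)] = DEAD

        in_tx = state == TX
        for k in np.unique(tx_year[in_tx]) if np.any(in_tx) else []:
            sel = in_tx & (tx_year == k)
            p_gf = annual_transition_probability(scenario.p_graft_failure, age, int(k))
            p_dt = annual_transition_probability(scenario.p_death_post_tx, age, int(k))
            tot = p_gf + p_dt
            sc = 1.0 / tot if tot > 1 else 1.0
            new_state[sel & (u < p_gf * sc)] = GF
            new_state[sel & (u >= p_gf * sc) & (u < (p_gf + p_dt) * sc)] = DEAD
            stay = sel & (u >= (p_gf + p_dt) * sc)
            new_tx_year[stay] = min(int(k) + 1, config.horizon)

        in_gf = state == GF
        new_state[in_gf & (u < p_dgf)] = DEAD

        state, tx_year = new_state, new_tx_year
        frac[t] = [
            np.mean(state == WAIT),
            np.mean(state == TX),
            np.mean(state == GF),
            np.mean(state == DEAD),
        ]
    return frac
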