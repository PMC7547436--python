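"""Parameter containers and structured-text I/O.

The model compares five deceased-donor kidney allocation strategies for
Australia: current practice and four longevity-matching variants (pairing
donor quality with recipient quality, or donor age with recipient age).
Each strategy is summarised by three Weibull proportional-hazards
transitions fitted from registry time-to-event data

* waitlist -> transplant          (time since listing)
* transplant -> graft failure    (time since transplant)
* transplant -> death            (time since transplant)

plus two fixed annual probabilities shared by every strategy (death on the
waitlist, death on dialysis after graft failure), state utilities and
annual state costs in 2018 Australian dollars.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping

import yaml

__all__ = [
    "WeibullHazardParams",
    "FixedAnnualProbability",
    "CumulativeIncidence",
    "AllocationScenario",
    "ModelConfig",
    "OPTION_IDS",
    "TRANSITIONS",
    "load_scenarios",
    "save_scenarios",
    "default_scenarios",
]

#: Canonical strategy identifiers, in league-table order.
OPTION_IDS = ("current", "option_1", "option_2", "option_3", "option_4")

#: The three Weibull transitions of every scenario, in canonical order.
TRANSITIONS = ("transplant", "graft_failure", "death_post_transplant")


@dataclass(frozen=True)
class WeibullHazardParams:
    """One Weibull proportional-hazards transition.

    Hazard ``h(t) = lam * gamma * t**(gamma-1) * exp(beta_age * age)`` so the
    cumulative hazard is ``H(t) = lam * exp(beta_age * age) * t**gamma``.

    ``lam`` is the rate parameter (per year**gamma), ``gamma`` the shape
    (dimensionless; >1 means rising hazard, <1 falling), ``beta_age`` the
    log-hazard increment per year of recipient age.  The ``sem_*`` fields are
    standard errors used only by the probabilistic sensitivity analysis.
    """

    lam: float
    gamma: float
    beta_age: float
    sem_lam: float = 0.0
    sem_gamma: float = 0.0
    sem_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        for name in ("sem_lam", "sem_gamma", "sem_beta"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class FixedAnnualProbability:
    """A time-constant annual transition probability with its standard error."""

    p: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"annual probability must be in [0, 1], got {self.p}")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass(frozen=True)
class CumulativeIncidence:
    """Event proportion ``p`` accrued over ``duration_T`` years."""

    p: float
    duration_T: float
    sem: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p < 1.0:
            raise ValueError(f"cumulative incidence must be in [0, 1), got {self.p}")
        if self.duration_T <= 0:
            raise ValueError("duration_T must be > 0")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")


@dataclass(frozen=True)
class AllocationScenario:
    """Full parameterisation of one allocation strategy.

    Costs are annual state payoffs in 2018 AUD; utilities are QALY weights.
    Waitlisted and post-graft-failure patients are on dialysis, so both
    states carry the dialysis cost and the dialysis utility.
    """

    name: str
    p_transplant: WeibullHazardParams
    p_graft_failure: WeibullHazardParams
    p_death_post_tx: WeibullHazardParams
    p_death_waitlist: FixedAnnualProbability
    p_death_post_gf: FixedAnnualProbability
    cost_tx_year1: float = 99_968.0
    cost_tx_subsequent: float = 13_916.0
    cost_dialysis: float = 81_689.34
    utility_transplant: float = 0.82
    utility_dialysis: float = 0.70

    def __post_init__(self) -> None:
        for name in ("cost_tx_year1", "cost_tx_subsequent", "cost_dialysis"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("utility_transplant", "utility_dialysis"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    def replace(self, **changes) -> "AllocationScenario":
        return dataclasses.replace(self, **changes)

    def weibull(self, transition: str) -> WeibullHazardParams:
        return {
            "transplant": self.p_transplant,
            "graft_failure": self.p_graft_failure,
            "death_post_transplant": self.p_death_post_tx,
        }[transition]


@dataclass(frozen=True)
class ModelConfig:
    """Run configuration of the cohort model.

    ``first_cycle_discounted``
        If False (default) the first cycle's payoffs are taken at full value
        and discounting starts from the second cycle, i.e. cycle *t* is
        weighted ``(1+r)**-(t-1)``.  If True, cycle *t* is weighted
        ``(1+r)**-t``.
    ``first_year_includes_maintenance``
        If True (default) the first transplanted year carries the one-time
        transplant cost plus the annual maintenance cost; if False it
        carries the one-time cost only.
    """

    cohort_size: float = 1000.0
    horizon: int = 20
    discount_rate: float = 0.05
    age: float = 50.0
    half_cycle_correction: bool = False
    first_cycle_discounted: bool = False
    first_year_includes_maintenance: bool = True

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be > 0")

    def discount_factor(self, cycle: int) -> float:
        """Discount weight of cycle ``cycle`` (1-based)."""
        exponent = cycle if self.first_cycle_discounted else cycle - 1
        return (1.0 + self.discount_rate) ** -exponent


# ---------------------------------------------------------------------------
# Structured-text I/O
# ---------------------------------------------------------------------------

def _scenario_from_mapping(name: str, weibull: Mapping, shared: Mapping) -> AllocationScenario:
    triples = {}
    for key in TRANSITIONS:
        row = weibull[key]
        triples[key] = WeibullHazardParams(
            lam=float(row["lam"]),
            gamma=float(row["gamma"]),
            beta_age=float(row["beta_age"]),
            sem_lam=float(row.get("sem_lam", 0.0)),
            sem_gamma=float(row.get("sem_gamma", 0.0)),
            sem_beta=float(row.get("sem_beta", 0.0)),
        )
    fp = shared["fixed_probabilities"]
    return AllocationScenario(
        name=name,
        p_transplant=triples["transplant"],
        p_graft_failure=triples["graft_failure"],
        p_death_post_tx=triples["death_post_transplant"],
        p_death_waitlist=FixedAnnualProbability(
            float(fp["death_waitlist"]["p"]), float(fp["death_waitlist"].get("sem", 0.0))
        ),
        p_death_post_gf=FixedAnnualProbability(
            float(fp["death_post_graft_failure"]["p"]),
            float(fp["death_post_graft_failure"].get("sem", 0.0)),
        ),
        cost_tx_year1=float(shared["costs_aud"]["transplant_first_year"]["value"]),
        cost_tx_subsequent=float(shared["costs_aud"]["transplant_subsequent_year"]["value"]),
        cost_dialysis=float(shared["costs_aud"]["dialysis"]["value"]),
        utility_transplant=float(shared["utilities"]["transplant"]["value"]),
        utility_dialysis=float(shared["utilities"]["dialysis"]["value"]),
    )


def load_scenarios(source) -> dict[str, AllocationScenario]:
    """Read a scenario parameter file (YAML path or open file object).

    Returns a dict keyed by option id, in file order.
    """
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    shared = doc["shared"]
    return {
        name: _scenario_from_mapping(name, weibull, shared)
        for name, weibull in doc["options"].items()
    }


def scenario_uncertainty(source=None) -> dict:
    """Return the shared uncertainty block (utility CIs, cost ranges, fixed-
    probability SEMs) of a parameter file; defaults to the packaged file."""
    if source is None:
        source = importlib.resources.files("renalloc.data") / "default_parameters.yaml"
        with source.open("r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    elif hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    return doc["shared"]


def save_scenarios(scenarios: Mapping[str, AllocationScenario], path) -> None:
    """Write scenarios back to YAML in the same layout ``load_scenarios`` reads.

    Shared blocks (costs, utilities, fixed probabilities) are taken from the
    first scenario; per-option overrides of shared quantities are not
    representable in this layout by design (the analysis assumes they are
    common to all arms).
    """
    first = next(iter(scenarios.values()))
    doc = {
        "currency": "AUD 2018",
        "shared": {
            "fixed_probabilities": {
                "death_waitlist": {
                    "p": first.p_death_waitlist.p,
                    "sem": first.p_death_waitlist.sem,
                    "distribution": "beta",
                },
                "death_post_graft_failure": {
                    "p": first.p_death_post_gf.p,
                    "sem": first.p_death_post_gf.sem,
                    "distribution": "beta",
                },
            },
            "utilities": {
                "transplant": {"value": first.utility_transplant, "distribution": "uniform"},
                "dialysis": {"value": first.utility_dialysis, "distribution": "uniform"},
            },
            "costs_aud": {
                "transplant_first_year": {"value": first.cost_tx_year1, "distribution": "uniform"},
                "transplant_subsequent_year": {
                    "value": first.cost_tx_subsequent,
                    "distribution": "uniform",
                },
                "dialysis": {"value": first.cost_dialysis, "distribution": "uniform"},
            },
        },
        "options": {},
    }
    for name, sc in scenarios.items():
        doc["options"][name] = {
            key: {
                "lam": wp.lam,
                "gamma": wp.gamma,
                "beta_age": wp.beta_age,
                "sem_lam": wp.sem_lam,
                "sem_gamma": wp.sem_gamma,
                "sem_beta": wp.sem_beta,
            }
            for key, wp in (
                ("transplant", sc.p_transplant),
                ("graft_failure", sc.p_graft_failure),
                ("death_post_transplant", sc.p_death_post_tx),
            )
        }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def default_scenarios() -> dict[str, AllocationScenario]:
    """The packaged parameter set for the Australian deceased-donor programme
    (registry-era Weibull estimates, 2018 AUD costs)."""
    resource = importlib.resources.files("renalloc.data") / "default_parameters.yaml"
    with resource.open("r", encoding="utf-8") as fh:
        return load_scenarios(fh)
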