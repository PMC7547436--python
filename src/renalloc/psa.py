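"""Probabilistic sensitivity analysis.

Every uncertain parameter is given a distribution: Weibull regression
coefficients are Normal(mean, SEM) with lam and gamma truncated at a small
positive floor; the two fixed annual probabilities are Beta with shape
parameters solved from (mean, SEM) by method of moments; utilities are
Uniform over their 95% CI; costs Uniform over +/-15% of the base value.

Costs, utilities and the fixed probabilities are common to all allocation
strategies, so one draw per iteration is shared across arms; the Weibull
triples are strategy-specific and drawn independently (no published
covariance).  Each parameter has its own named, seeded random stream, so
results are invariant to iteration order and to the subset of options
evaluated.

``probability_of_error`` follows the decision-uncertainty convention of the
analysis: the probability that an option's incremental net monetary
benefit against current practice is not positive (rule ``vs_current``).
The stricter rule counting an option as correct only when it attains the
strictly highest NMB among all arms is available as ``vs_all``; ties count
as non-highest under both rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort
from .econ import WtpThreshold
from .parameters import (
    AllocationScenario,
    FixedAnnualProbability,
    ModelConfig,
    WeibullHazardParams,
    scenario_uncertainty,
)

__all__ = [
    "ParameterDistributionSpec",
    "PsaRun",
    "PsaSummary",
    "build_default_specs",
    "sample_scenario",
    "run_psa",
    "probability_of_error",
    "summarize_psa",
    "ceac",
]

_LAM_GAMMA_FLOOR = 1e-8

#: scenario attribute touched by each shared spec target
_SHARED_TARGETS = {
    "shared.p_death_waitlist": "p_death_waitlist",
    "shared.p_death_post_gf": "p_death_post_gf",
    "shared.utility_transplant": "utility_transplant",
    "shared.utility_dialysis": "utility_dialysis",
    "shared.cost_tx_year1": "cost_tx_year1",
    "shared.cost_tx_subsequent": "cost_tx_subsequent",
    "shared.cost_dialysis": "cost_dialysis",
}

_WEIBULL_FIELDS = {
    "transplant": "p_transplant",
    "graft_failure": "p_graft_failure",
    "death_post_transplant": "p_death_post_tx",
}


@dataclass(frozen=True)
class ParameterDistributionSpec:
    """One sampled parameter.

    ``target`` is a dotted path: ``shared.<field>`` for arm-common
    parameters or ``<option>.<transition>.<coef>`` for Weibull coefficients
    (``coef`` in lam/gamma/beta_age).  ``family`` is ``normal`` with args
    (mean, sem), ``beta`` with args (mean, sem), or ``uniform`` with args
    (low, high).  ``truncation`` optionally clips draws to [low, high].
    """

    target: str
    family: str
    args: tuple
    truncation: tuple | None = None

    def __post_init__(self) -> None:
        if self.family not in ("normal", "beta", "uniform"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "uniform" and not self.args[0] <= self.args[1]:
            raise ValueError("uniform requires low <= high")
        if self.family == "beta":
            mean, sem = self.args
            if not 0 < mean < 1:
                raise ValueError("beta mean must be in (0, 1)")
            if sem > 0 and sem**2 >= mean * (1 - mean):
                raise ValueError("infeasible beta moments: sem^2 >= mean(1-mean)")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "normal":
            mean, sem = self.args
            out = rng.normal(mean, sem, size) if sem > 0 else np.full(size, mean)
        elif self.family == "uniform":
            low, high = self.args
            out = rng.uniform(low, high, size) if high > low else np.full(size, float(low))
        else:  # beta, method of moments
            mean, sem = self.args
            if sem == 0:
                out = np.full(size, mean)
            else:
                nu = mean * (1 - mean) / sem**2 - 1.0
                out = rng.beta(mean * nu, (1 - mean) * nu, size)
        if self.truncation is not None:
            low, high = self.truncation
            out = np.clip(out, low if low is not None else -np.inf, high if high is not None else np.inf)
        return out


def build_default_specs(
    scenarios: Mapping[str, AllocationScenario],
    uncertainty: Mapping | None = None,
) -> list[ParameterDistributionSpec]:
    """Distribution specs for a scenario set.

    Weibull coefficients get Normal(mean, SEM) from the scenarios' own SEM
    fields; shared utilities, costs and fixed probabilities use the
    uncertainty block of the packaged parameter file unless ``uncertainty``
    overrides it.
    """
    unc = uncertainty if uncertainty is not None else scenario_uncertainty()
    first = next(iter(scenarios.values()))
    specs: list[ParameterDistributionSpec] = []

    fp = unc["fixed_probabilities"]
    specs.append(
        ParameterDistributionSpec(
            "shared.p_death_waitlist", "beta",
            (first.p_death_waitlist.p, float(fp["death_waitlist"].get("sem", 0.0))),
        )
    )
    specs.append(
        ParameterDistributionSpec(
            "shared.p_death_post_gf", "beta",
            (first.p_death_post_gf.p, float(fp["death_post_graft_failure"].get("sem", 0.0))),
        )
    )
    ut = unc["utilities"]
    specs.append(
        ParameterDistributionSpec(
            "shared.utility_transplant", "uniform",
            (float(ut["transplant"]["ci_low"]), float(ut["transplant"]["ci_high"])),
        )
    )
    specs.append(
        ParameterDistributionSpec(
            "shared.utility_dialysis", "uniform",
            (float(ut["dialysis"]["ci_low"]), float(ut["dialysis"]["ci_high"])),
        )
    )
    costs = unc["costs_aud"]
    for target, attr, key in (
        ("shared.cost_tx_year1", "cost_tx_year1", "transplant_first_year"),
        ("shared.cost_tx_subsequent", "cost_tx_subsequent", "transplant_subsequent_year"),
        ("shared.cost_dialysis", "cost_dialysis", "dialysis"),
    ):
        base = getattr(first, attr)
        rel = float(costs[key].get("rel_range", 0.15))
        specs.append(
            ParameterDistributionSpec(target, "uniform", (base * (1 - rel), base * (1 + rel)))
        )

    for name, sc in scenarios.items():
        for transition, attr in _WEIBULL_FIELDS.items():
            wp: WeibullHazardParams = getattr(sc, attr)
            for coef, mean, sem in (
                ("lam", wp.lam, wp.sem_lam),
                ("gamma", wp.gamma, wp.sem_gamma),
                ("beta_age", wp.beta_age, wp.sem_beta),
            ):
                trunc = (_LAM_GAMMA_FLOOR, None) if coef in ("lam", "gamma") else None
                specs.append(
                    ParameterDistributionSpec(
                        f"{name}.{transition}.{coef}", "normal", (mean, sem), trunc
                    )
                )
    return specs


def _named_streams(specs: Sequence[ParameterDistributionSpec], seed: int):
    """One independent, deterministic random stream per parameter target."""
    targets = sorted(spec.target for spec in specs)
    if len(targets) != len(set(targets)):
        raise ValueError("duplicate spec targets")
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(targets))
    order = {t: i for i, t in enumerate(targets)}
    return {spec.target: np.random.default_rng(children[order[spec.target]]) for spec in specs}


def _draw_all(
    specs: Sequence[ParameterDistributionSpec], seed: int, size: int
) -> dict[str, np.ndarray]:
    streams = _named_streams(specs, seed)
    return {spec.target: spec.draw(streams[spec.target], size) for spec in specs}


def sample_scenario(
    base: AllocationScenario,
    specs: Sequence[ParameterDistributionSpec],
    rng: np.random.Generator,
) -> AllocationScenario:
    """Draw one perturbed copy of ``base``.

    Applies every spec targeting ``shared.*`` or ``<base.name>.*``, drawing
    sequentially from ``rng`` in sorted target order.  With all
    distributions degenerate (zero SEMs, collapsed ranges) the base
    scenario is returned exactly.
    """
    changes: dict = {}
    weibull_updates: dict[str, dict[str, float]] = {}
    for spec in sorted(specs, key=lambda s: s.target):
        parts = spec.target.split(".")
        if parts[0] == "shared":
            attr = _SHARED_TARGETS[spec.target]
            value = float(spec.draw(rng, 1)[0])
            if attr in ("p_death_waitlist", "p_death_post_gf"):
                old = getattr(base, attr)
                changes[attr] = FixedAnnualProbability(value, old.sem)
            else:
                changes[attr] = value
        elif parts[0] == base.name:
            _, transition, coef = parts
            weibull_updates.setdefault(transition, {})[coef] = float(spec.draw(rng, 1)[0])
    for transition, coefs in weibull_updates.items():
        attr = _WEIBULL_FIELDS[transition]
        old: WeibullHazardParams = getattr(base, attr)
        changes[attr] = WeibullHazardParams(
            lam=coefs.get("lam", old.lam),
            gamma=coefs.get("gamma", old.gamma),
            beta_age=coefs.get("beta_age", old.beta_age),
            sem_lam=old.sem_lam,
            sem_gamma=old.sem_gamma,
            sem_beta=old.sem_beta,
        )
    return base.replace(**changes)


@dataclass(frozen=True)
class PsaRun:
    """Per-iteration Monte-Carlo results for every strategy."""

    n_iterations: int
    seed: int
    wtp: WtpThreshold
    comparator: str
    options: tuple[str, ...]
    costs: dict[str, np.ndarray]
    qalys: dict[str, np.ndarray]

    def nmb(self, option: str, wtp: float | None = None) -> np.ndarray:
        w = self.wtp.value if wtp is None else float(wtp)
        return w * self.qalys[option] - self.costs[option]

    def incremental(self, option: str, wtp: float | None = None):
        """(delta cost, delta qaly, incremental NMB) arrays vs the comparator."""
        d_cost = self.costs[option] - self.costs[self.comparator]
        d_qaly = self.qalys[option] - self.qalys[self.comparator]
        return d_cost, d_qaly, self.nmb(option, wtp) - self.nmb(self.comparator, wtp)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {
                    "iteration": np.arange(self.n_iterations),
                    "option": option,
                    "cost": self.costs[option],
                    "qaly": self.qalys[option],
                    "nmb": self.nmb(option),
                }
            )
            for option in self.options
        ]
        return pd.concat(frames, ignore_index=True)


def run_psa(
    scenarios: Mapping[str, AllocationScenario],
    config: ModelConfig,
    n_iterations: int = 20_000,
    seed: int = 0,
    wtp: WtpThreshold | float = 28_000.0,
    specs: Sequence[ParameterDistributionSpec] | None = None,
    comparator: str = "current",
) -> PsaRun:
    """Monte-Carlo PSA: every strategy re-evaluated under sampled parameters.

    Shared parameters use one draw per iteration across all arms; Weibull
    coefficients are drawn per arm.  Fully reproducible given ``seed``.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if comparator not in scenarios:
        raise KeyError(f"comparator {comparator!r} not among scenarios")
    if specs is None:
        specs = build_default_specs(scenarios)
    wtp = wtp if isinstance(wtp, WtpThreshold) else WtpThreshold(float(wtp))

    draws = _draw_all(specs, seed, n_iterations)
    shared_map = {
        "p_death_waitlist": "shared.p_death_waitlist",
        "p_death_post_gf": "shared.p_death_post_gf",
        "cost_tx_year1": "shared.cost_tx_year1",
        "cost_tx_subsequent": "shared.cost_tx_subsequent",
        "cost_dialysis": "shared.cost_dialysis",
        "utility_transplant": "shared.utility_transplant",
        "utility_dialysis": "shared.utility_dialysis",
    }
    costs: dict[str, np.ndarray] = {}
    qalys: dict[str, np.ndarray] = {}
    for name, sc in scenarios.items():
        params = cohort.scenario_param_arrays(sc, n_iterations)
        for attr, target in shared_map.items():
            if target in draws:
                params[attr] = draws[target]
        weibull_map = {
            "transplant": ("lam_tx", "gamma_tx", "beta_tx"),
            "graft_failure": ("lam_gf", "gamma_gf", "beta_gf"),
            "death_post_transplant": ("lam_dtx", "gamma_dtx", "beta_dtx"),
        }
        for transition, keys in weibull_map.items():
            for coef, key in zip(("lam", "gamma", "beta_age"), keys):
                target = f"{name}.{transition}.{coef}"
                if target in draws:
                    params[key] = draws[target]
        costs[name], qalys[name] = cohort.batch_outcomes(params, config)

    return PsaRun(
        n_iterations=n_iterations,
        seed=seed,
        wtp=wtp,
        comparator=comparator,
        options=tuple(scenarios),
        costs=costs,
        qalys=qalys,
    )


def probability_of_error(
    run: PsaRun, option: str, rule: str = "vs_current", wtp: float | None = None
) -> float:
    """Probability that choosing ``option`` over current practice is wrong.

    ``vs_current``: fraction of iterations with incremental NMB <= 0 against
    the comparator.  ``vs_all``: one minus the fraction of iterations in
    which the option attains the strictly highest NMB among every arm
    (ties count as non-highest).
    """
    if option not in run.options:
        raise KeyError(f"unknown option {option!r}")
    if rule == "vs_current":
        _, _, inmb = run.incremental(option, wtp)
        return float(np.mean(inmb <= 0.0))
    if rule == "vs_all":
        own = run.nmb(option, wtp)
        others = [run.nmb(o, wtp) for o in run.options if o != option]
        strictly_best = np.all(own[None, :] > np.stack(others), axis=0)
        return float(1.0 - np.mean(strictly_best))
    raise ValueError(f"unknown rule {rule!r}")


@dataclass(frozen=True)
class PsaSummary:
    """Mean and range of the incremental quantities, plus decision error."""

    wtp: float
    comparator: str
    table: pd.DataFrame = field(repr=False)

    def ordering(self) -> list[str]:
        """Options ranked by mean incremental NMB, best first."""
        return list(self.table.sort_values("inmb_mean", ascending=False)["option"])


def summarize_psa(run: PsaRun, wtp: float | None = None) -> PsaSummary:
    """Per-option means and min-max ranges of incremental cost / QALY / NMB
    versus the comparator, with both error probabilities."""
    w = run.wtp.value if wtp is None else float(wtp)
    rows = []
    for option in run.options:
        if option == run.comparator:
            continue
        d_cost, d_qaly, inmb = run.incremental(option, w)
        rows.append(
            {
                "option": option,
                "delta_cost_mean": d_cost.mean(),
                "delta_cost_min": d_cost.min(),
                "delta_cost_max": d_cost.max(),
                "delta_qaly_mean": d_qaly.mean(),
                "delta_qaly_min": d_qaly.min(),
                "delta_qaly_max": d_qaly.max(),
                "inmb_mean": inmb.mean(),
                "inmb_min": inmb.min(),
                "inmb_max": inmb.max(),
                "prob_error_vs_current": probability_of_error(run, option, "vs_current", w),
                "prob_error_vs_all": probability_of_error(run, option, "vs_all", w),
            }
        )
    return PsaSummary(wtp=w, comparator=run.comparator, table=pd.DataFrame(rows))


def ceac(run: PsaRun, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability: P(strictly highest NMB) per WTP.

    Ties count toward no arm, so the per-WTP probabilities sum to at most 1
    (exactly 1 when ties have measure zero).
    """
    rows = []
    for w in wtp_grid:
        nmbs = np.stack([run.nmb(o, w) for o in run.options])
        best = nmbs.max(axis=0)
        unique_best = np.sum(nmbs >= best, axis=0) == 1
        winner = nmbs.argmax(axis=0)
        for i, option in enumerate(run.options):
            rows.append(
                {
                    "wtp": float(w),
                    "option": option,
                    "probability_best": float(np.mean(unique_best & (winner == i))),
                }
            )
    return pd.DataFrame(rows)
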