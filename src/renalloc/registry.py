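"""Synthetic patient-level registry with the structure the analysis assumes.

The real analysis links a national dialysis-and-transplant registry:
waitlisted patients (age, recipient-quality EPTS score, transplant or death
or censoring times) joined to donor information (donor age, donor-quality
KDRI score) and post-transplant outcomes, plus a second cohort of dialysis
patients contributing post-graft-failure survival.  That linkage is
restricted, so this module generates data with the same statistical
skeleton: Weibull proportional-hazards event times for transplant, graft
failure and post-transplant death; annual (geometric-in-years) death
processes on the waitlist and after graft failure; administrative censoring
at a fixed horizon.

Donor/recipient quality scores are monotone noisy functions of age
(lognormal multiplicative noise on a linear ramp), which gives the
threshold-based allocation rules realistic overlap; they are NOT calibrated
to any real KDRI/EPTS marginal distribution.

Latent competing events are resolved by drawing all latent times and
keeping the earliest, ties broken in favour of death.  The observed history
of a record therefore contains at most one terminal event.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .parameters import FixedAnnualProbability, WeibullHazardParams

__all__ = [
    "GenerationConfig",
    "generate_registry",
    "generate_post_graft_failure_cohort",
    "apply_allocation_option",
    "write_registry",
    "read_registry",
    "REGISTRY_COLUMNS",
    "ALLOCATION_RULES",
]

#: Column order of the registry table (see docs/data_dictionary.md).
REGISTRY_COLUMNS = [
    "patient_id",
    "age_at_listing",
    "epts",
    "listed_time",
    "transplant_time",
    "donor_age",
    "donor_kdri",
    "graft_failure_time",
    "death_time",
    "censor_time",
]


def _default_age_dist() -> dict:
    return {"kind": "truncnorm", "mean": 50.0, "sd": 13.0, "low": 18.0, "high": 80.0}


def _default_donor_age_dist() -> dict:
    return {"kind": "truncnorm", "mean": 45.0, "sd": 15.0, "low": 5.0, "high": 80.0}


def _default_score_model() -> dict:
    # linear ramp x lognormal noise, chosen so the allocation thresholds
    # (EPTS 1.033 / 2.4806 at the 20th / 80th centile, KDRI 0.9148 / 1.7208)
    # split the synthetic population near the intended quantiles
    return {
        "epts_intercept": 0.0,
        "epts_slope": 0.034,
        "epts_sigma": 0.40,
        "kdri_intercept": 0.35,
        "kdri_slope": 0.021,
        "kdri_sigma": 0.30,
    }


@dataclass(frozen=True)
class GenerationConfig:
    """Inputs of :func:`generate_registry`.

    ``hazard_params`` holds one :class:`WeibullHazardParams` per transition
    key ``transplant``, ``graft_failure``, ``death_post_transplant``;
    ``fixed_probs`` the annual probabilities for ``death_waitlist`` and
    ``death_post_graft_failure``.  ``censor_horizon`` is the administrative
    follow-up in years from listing.
    """

    n_patients: int
    seed: int
    hazard_params: Mapping[str, WeibullHazardParams]
    fixed_probs: Mapping[str, FixedAnnualProbability]
    censor_horizon: float = 11.0
    age_distribution: Mapping = field(default_factory=_default_age_dist)
    donor_age_distribution: Mapping = field(default_factory=_default_donor_age_dist)
    epts_kdri_model: Mapping = field(default_factory=_default_score_model)

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.censor_horizon <= 0:
            raise ValueError("censor_horizon must be > 0")
        for key in ("transplant", "graft_failure", "death_post_transplant"):
            if key not in self.hazard_params:
                raise ValueError(f"hazard_params missing transition {key!r}")
        for key in ("death_waitlist", "death_post_graft_failure"):
            if key not in self.fixed_probs:
                raise ValueError(f"fixed_probs missing {key!r}")


def _draw_bounded_age(spec: Mapping, n: int, rng: np.random.Generator) -> np.ndarray:
    if spec.get("kind", "truncnorm") != "truncnorm":
        raise ValueError(f"unsupported age distribution kind {spec.get('kind')!r}")
    mean, sd = float(spec["mean"]), float(spec["sd"])
    low, high = float(spec["low"]), float(spec["high"])
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _weibull_ph_times(
    params: WeibullHazardParams, ages: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inverse-CDF draw: T = (E / (lam e^{beta a}))^(1/gamma), E ~ Exp(1).

    A zero rate parameter gives an infinite latent time (event never occurs).
    """
    scale = params.lam * np.exp(params.beta_age * ages)
    e = rng.exponential(size=ages.size)
    with np.errstate(divide="ignore"):
        return np.where(scale > 0, (e / np.where(scale > 0, scale, 1.0)) ** (1.0 / params.gamma), np.inf)


def _geometric_years(p: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Integer-year event times for an annual-probability process (inf if p=0)."""
    if p <= 0:
        return np.full(n, np.inf)
    return rng.geometric(p, size=n).astype(float)


def generate_registry(config: GenerationConfig) -> pd.DataFrame:
    """Generate the linked waitlist/transplant registry table.

    Returns a DataFrame with :data:`REGISTRY_COLUMNS`; times are years
    (transplant and waitlist outcomes from listing, post-transplant outcomes
    from transplant), missing values are NaN.  Identical seeds give
    identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ages = _draw_bounded_age(config.age_distribution, n, rng)
    sm = config.epts_kdri_model
    epts = (sm["epts_intercept"] + sm["epts_slope"] * ages) * np.exp(
        sm["epts_sigma"] * rng.standard_normal(n)
    )

    horizon = config.censor_horizon
    t_tx = _weibull_ph_times(config.hazard_params["transplant"], ages, rng)
    t_death_wl = _geometric_years(config.fixed_probs["death_waitlist"].p, n, rng)

    # competing resolution on the waitlist clock; ties favour death
    transplanted = (t_tx < t_death_wl) & (t_tx < horizon)
    died_waitlisted = ~transplanted & (t_death_wl <= horizon)

    donor_ages = np.full(n, np.nan)
    kdri = np.full(n, np.nan)
    n_tx = int(transplanted.sum())
    if n_tx:
        d_ages = _draw_bounded_age(config.donor_age_distribution, n_tx, rng)
        donor_ages[transplanted] = d_ages
        kdri[transplanted] = (sm["kdri_intercept"] + sm["kdri_slope"] * d_ages) * np.exp(
            sm["kdri_sigma"] * rng.standard_normal(n_tx)
        )

    # post-transplant clock: latent graft failure and death, earliest wins
    graft_failure_time = np.full(n, np.nan)
    death_time = np.full(n, np.nan)
    censor_time = np.where(transplanted, horizon - t_tx, horizon)
    if n_tx:
        tx_ages = ages[transplanted]
        t_gf = _weibull_ph_times(config.hazard_params["graft_failure"], tx_ages, rng)
        t_dtx = _weibull_ph_times(config.hazard_params["death_post_transplant"], tx_ages, rng)
        followup = horizon - t_tx[transplanted]
        gf_first = (t_gf < t_dtx) & (t_gf < followup)
        death_first = (t_dtx <= t_gf) & (t_dtx < followup)  # ties favour death
        gf_col = np.full(n_tx, np.nan)
        gf_col[gf_first] = t_gf[gf_first]
        d_col = np.full(n_tx, np.nan)
        d_col[death_first] = t_dtx[death_first]
        graft_failure_time[transplanted] = gf_col
        death_time[transplanted] = d_col
    death_time[died_waitlisted] = t_death_wl[died_waitlisted]

    transplant_time = np.where(transplanted, t_tx, np.nan)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(n)],
            "age_at_listing": ages,
            "epts": epts,
            "listed_time": np.zeros(n),
            "transplant_time": transplant_time,
            "donor_age": donor_ages,
            "donor_kdri": kdri,
            "graft_failure_time": graft_failure_time,
            "death_time": death_time,
            "censor_time": censor_time,
        }
    )


def generate_post_graft_failure_cohort(
    n_patients: int,
    annual_death_probability: float,
    censor_horizon: float,
    seed: int,
) -> pd.DataFrame:
    """Second linked dataset: dialysis survival after graft failure.

    Death occurs at integer years with the given annual probability;
    administrative censoring at ``censor_horizon``.  Columns: ``time``
    (years on dialysis), ``event`` (1 = died).
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rng = np.random.default_rng(seed)
    t_death = _geometric_years(annual_death_probability, n_patients, rng)
    event = t_death <= censor_horizon
    time = np.minimum(t_death, censor_horizon)
    return pd.DataFrame({"time": time, "event": event.astype(int)})


# ---------------------------------------------------------------------------
# Allocation-option subsetting
# ---------------------------------------------------------------------------

#: (kind, donor threshold, recipient threshold, best-stratum comparison).
#: "best-with-best": records pair low-with-low or high-with-high;
#: thresholds are inclusive on the stratum named first.
ALLOCATION_RULES = {
    "option_1": ("score", 0.9148, 1.033, "le"),  # best 20% KDRI with best 20% EPTS
    "option_2": ("score", 1.7208, 2.4806, "ge"),  # worst 20% KDRI with worst 20% EPTS
    "option_3": ("age", 32.0, 41.0, "le"),  # youngest 25% donors with youngest 25% recipients
    "option_4": ("age", 58.0, 60.0, "ge"),  # oldest 25% donors with oldest 25% recipients
}

_OPTION_ALIASES = {
    "current": "current",
    "1": "option_1",
    "2": "option_2",
    "3": "option_3",
    "4": "option_4",
    "option_1": "option_1",
    "option_2": "option_2",
    "option_3": "option_3",
    "option_4": "option_4",
}


def apply_allocation_option(records: pd.DataFrame, option) -> pd.DataFrame:
    """Subset transplanted records to those conforming to an allocation rule.

    Transplanted records violating the rule's pairing (e.g. a best-quintile
    kidney implanted in a non-best recipient under option 1) are EXCLUDED,
    mirroring how the hypothetical-option datasets are carved out of the
    observed registry; untransplanted records pass through unchanged.
    ``current`` is the identity.  Age rules compare donor age with recipient
    age *at transplant* (listing age plus waiting time).
    """
    key = _OPTION_ALIASES.get(str(option))
    if key is None:
        raise ValueError(f"unknown allocation option {option!r}")
    if key == "current":
        return records.copy()

    kind, donor_thresh, recip_thresh, best_cmp = ALLOCATION_RULES[key]
    transplanted = records["transplant_time"].notna()
    if kind == "score":
        donor_val = records["donor_kdri"]
        recip_val = records["epts"]
    else:
        donor_val = records["donor_age"]
        recip_val = records["age_at_listing"] + records["transplant_time"]

    if best_cmp == "le":
        in_stratum_donor = donor_val <= donor_thresh
        in_stratum_recip = recip_val <= recip_thresh
    else:
        in_stratum_donor = donor_val >= donor_thresh
        in_stratum_recip = recip_val >= recip_thresh
    conforming = in_stratum_donor == in_stratum_recip

    keep = ~transplanted | conforming
    return records.loc[keep].copy()


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

def write_registry(records: pd.DataFrame, path) -> None:
    """Write the registry as CSV, missing values as empty fields."""
    records.to_csv(path, index=False, columns=REGISTRY_COLUMNS, na_rep="")


def read_registry(path) -> pd.DataFrame:
    """Read a registry CSV written by :func:`write_registry`."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(REGISTRY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"registry file missing columns: {sorted(missing)}")
    return df[REGISTRY_COLUMNS]
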