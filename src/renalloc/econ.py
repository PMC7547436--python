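"""Incremental cost-effectiveness: ICERs, dominance, net monetary benefit.

Conventions
-----------
* ICER = (cost_intervention - cost_comparator) / (qaly_intervention -
  qaly_comparator); undefined when the QALY difference is zero.
* A strategy is *dominant* when it saves cost and gains QALYs, *dominated*
  when it costs more and loses QALYs; the two mixed quadrants are reported
  with their signed ICER.
* NMB = WTP x QALY - cost; incremental NMB is the difference of absolute
  NMBs against the comparator, positive meaning cost-effective at that
  willingness-to-pay.
* League tables print ICERs truncated toward zero (integer AUD/QALY), the
  usual rendering in published tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .cohort import EconomicResult

__all__ = [
    "WtpThreshold",
    "ComparisonResult",
    "compute_icer",
    "compute_nmb",
    "incremental_nmb",
    "wtp_ordering",
    "league_table",
    "DOMINANT",
    "DOMINATED",
]

DOMINANT = "dominant (cost saving, more effective)"
DOMINATED = "dominated (more costly, less effective)"


@dataclass(frozen=True)
class WtpThreshold:
    """Willingness to pay for one QALY, in AUD."""

    value: float

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("WTP threshold must be > 0")


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise comparison of an intervention against a comparator."""

    delta_cost: float
    delta_qaly: float
    icer: float  # nan when delta_qaly == 0
    dominance_label: str

    @property
    def icer_defined(self) -> bool:
        return not math.isnan(self.icer)

    def icer_truncated(self) -> int:
        """ICER truncated toward zero, for league-table rendering."""
        if not self.icer_defined:
            raise ValueError("ICER undefined (equal effectiveness)")
        return math.trunc(self.icer)


def compute_icer(intervention: EconomicResult, comparator: EconomicResult) -> ComparisonResult:
    """Incremental cost, incremental QALYs and ICER/dominance classification."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    if d_qaly == 0.0:
        label = f"equal effectiveness (cost difference {d_cost:+,.0f} AUD)"
        return ComparisonResult(d_cost, d_qaly, math.nan, label)
    icer = d_cost / d_qaly
    if d_cost < 0 and d_qaly > 0:
        label = DOMINANT
    elif d_cost > 0 and d_qaly < 0:
        label = DOMINATED
    elif d_qaly > 0:
        label = "more costly, more effective"
    else:
        label = "less costly, less effective"
    return ComparisonResult(d_cost, d_qaly, icer, label)


def compute_nmb(result: EconomicResult, wtp: WtpThreshold | float) -> float:
    """Absolute net monetary benefit, WTP x QALY - cost."""
    w = wtp.value if isinstance(wtp, WtpThreshold) else float(wtp)
    return w * result.total_qaly - result.total_cost


def incremental_nmb(
    option_result: EconomicResult,
    current_result: EconomicResult,
    wtp: WtpThreshold | float,
) -> float:
    """NMB of the option minus NMB of current practice at the same WTP."""
    return compute_nmb(option_result, wtp) - compute_nmb(current_result, wtp)


def wtp_ordering(
    results: Mapping[str, EconomicResult],
    wtp_list: Sequence[WtpThreshold | float],
    comparator: str = "current",
) -> dict[float, list[str]]:
    """Rank the non-comparator options by incremental NMB at each threshold.

    Returns ``{wtp_value: [best option, ..., worst option]}``.
    """
    if comparator not in results:
        raise KeyError(f"comparator {comparator!r} not among results")
    if len(results) < 2:
        raise ValueError("need at least two strategies to rank")
    base = results[comparator]
    out: dict[float, list[str]] = {}
    for wtp in wtp_list:
        w = wtp.value if isinstance(wtp, WtpThreshold) else float(wtp)
        inmb = {
            name: incremental_nmb(res, base, w)
            for name, res in results.items()
            if name != comparator
        }
        out[w] = sorted(inmb, key=inmb.get, reverse=True)
    return out


def league_table(
    results: Mapping[str, EconomicResult], comparator: str = "current"
) -> pd.DataFrame:
    """Base-case league table: totals, cost per QALY, ICER-or-dominance.

    Costs are rendered in millions; ICERs truncated toward zero.  The
    comparator row carries an empty ICER cell.
    """
    if comparator not in results:
        raise KeyError(f"comparator {comparator!r} not among results")
    base = results[comparator]
    rows = []
    for name, res in results.items():
        if name == comparator:
            icer_cell = ""
        else:
            cmp_res = compute_icer(res, base)
            if cmp_res.dominance_label == DOMINANT or not cmp_res.icer_defined:
                icer_cell = cmp_res.dominance_label
            else:
                icer_cell = f"{cmp_res.icer_truncated()} ({cmp_res.dominance_label})"
        rows.append(
            {
                "option": name,
                "total_cost_millions": res.total_cost / 1e6,
                "total_qaly": res.total_qaly,
                "cost_per_qaly": res.total_cost / res.total_qaly,
                "icer_vs_comparator": icer_cell,
            }
        )
    return pd.DataFrame(rows)
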