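"""Comparative cost-effectiveness outcomes.

Turns per-strategy cohort results into incremental costs and effects, ICERs
with explicit dominance handling, willingness-to-pay classification and
fractures averted.  ICERs are computed from full-precision model outputs;
rounding is left to the reporting layer.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .markov_cohort import StrategyResult
from .parameters import ModelParameters

__all__ = [
    "ComparisonError",
    "Dominance",
    "CEAClass",
    "PairwiseComparison",
    "CEAResult",
    "icer",
    "classify_wtp",
    "compare_strategies",
]


class ComparisonError(Exception):
    """Strategies were run under incompatible settings."""


class Dominance(enum.Enum):
    COST_SAVING = "cost_saving"   # cheaper and more effective: no meaningful ratio
    DOMINATED = "dominated"       # dearer and less effective
    UNDEFINED = "undefined"       # zero QALY difference


class CEAClass(enum.Enum):
    COST_SAVING = "cost_saving"
    HIGHLY_COST_EFFECTIVE = "highly_cost_effective"
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"
    DOMINATED = "dominated"
    UNDEFINED = "undefined"


def icer(delta_cost: float, delta_qalys: float) -> float | Dominance:
    """Incremental cost-effectiveness ratio or a dominance marker.

    A numeric ratio is returned when the strategy trades money for health
    (both deltas positive) or sits in the south-west quadrant (both
    negative, interpreted as savings per QALY forgone).  Cheaper-and-better
    yields ``COST_SAVING``, dearer-and-worse ``DOMINATED``, and a zero QALY
    difference ``UNDEFINED``.
    """
    if delta_qalys == 0.0:
        return Dominance.UNDEFINED
    if delta_qalys > 0.0 and delta_cost <= 0.0:
        return Dominance.COST_SAVING
    if delta_qalys < 0.0 and delta_cost >= 0.0:
        return Dominance.DOMINATED
    return delta_cost / delta_qalys


def classify_wtp(
    icer_value: float | Dominance,
    wtp_primary: float,
    wtp_upper: float,
) -> CEAClass:
    """Classify an ICER against the two willingness-to-pay thresholds
    (1x and 3x GDP per capita in the base case)."""
    if not (wtp_primary > 0 and wtp_primary < wtp_upper):
        raise ComparisonError("need 0 < wtp_primary < wtp_upper")
    if isinstance(icer_value, Dominance):
        return {
            Dominance.COST_SAVING: CEAClass.COST_SAVING,
            Dominance.DOMINATED: CEAClass.DOMINATED,
            Dominance.UNDEFINED: CEAClass.UNDEFINED,
        }[icer_value]
    if icer_value <= wtp_primary:
        return CEAClass.HIGHLY_COST_EFFECTIVE
    if icer_value <= wtp_upper:
        return CEAClass.COST_EFFECTIVE
    return CEAClass.NOT_COST_EFFECTIVE


@dataclass
class PairwiseComparison:
    strategy: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    vf_averted: float
    icer: float | Dominance
    classification: CEAClass


@dataclass
class CEAResult:
    """Per-strategy totals plus every labeled pairwise comparison."""

    strategies: dict[str, StrategyResult]
    pairwise: list[PairwiseComparison]
    wtp_primary: float
    wtp_upper: float

    def pair(self, strategy: str, comparator: str) -> PairwiseComparison:
        for p in self.pairwise:
            if p.strategy == strategy and p.comparator == comparator:
                return p
        raise KeyError(f"no comparison {strategy} vs {comparator}")

    def summary_frame(self) -> pd.DataFrame:
        rows = [
            {
                "strategy": name,
                "cumulative_discounted_cost": r.cumulative_discounted_cost,
                "cumulative_discounted_qalys": r.cumulative_discounted_qalys,
                "vf_events": r.total_vf_events,
            }
            for name, r in self.strategies.items()
        ]
        return pd.DataFrame(rows)

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.pairwise:
            val = p.icer
            rows.append({
                "strategy": p.strategy,
                "comparator": p.comparator,
                "delta_cost": p.delta_cost,
                "delta_qalys": p.delta_qalys,
                "vf_averted": p.vf_averted,
                "icer": val if not isinstance(val, Dominance) else math.nan,
                "icer_marker": val.value if isinstance(val, Dominance) else "",
                "classification": p.classification.value,
            })
        return pd.DataFrame(rows)


def _check_consistent(results: list[StrategyResult], params: ModelParameters) -> None:
    for r in results:
        if r.cohort_size != params.econ.cohort_size:
            raise ComparisonError(
                f"strategy {r.strategy!r} ran at cohort size {r.cohort_size}, "
                f"expected {params.econ.cohort_size}")
        if len(r.trace) != params.econ.horizon_years:
            raise ComparisonError(
                f"strategy {r.strategy!r} ran {len(r.trace)} cycles, "
                f"expected {params.econ.horizon_years}")


def compare_strategies(
    results: list[StrategyResult],
    params: ModelParameters,
) -> CEAResult:
    """All ordered pairwise comparisons among the supplied strategy runs.

    ``vf_averted`` is VF(comparator) - VF(strategy): positive when the
    strategy prevents fractures relative to its comparator.
    """
    if len(results) < 2:
        raise ComparisonError("need at least two strategies to compare")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ComparisonError(f"duplicate strategy names: {names}")
    _check_consistent(results, params)

    by_name = {r.strategy: r for r in results}
    wtp_lo = params.econ.wtp_primary
    wtp_hi = params.econ.wtp_upper
    pairwise = []
    for a in results:
        for b in results:
            if a.strategy == b.strategy:
                continue
            dc = a.cumulative_discounted_cost - b.cumulative_discounted_cost
            dq = a.cumulative_discounted_qalys - b.cumulative_discounted_qalys
            ratio = icer(dc, dq)
            pairwise.append(PairwiseComparison(
                strategy=a.strategy,
                comparator=b.strategy,
                delta_cost=dc,
                delta_qalys=dq,
                vf_averted=b.total_vf_events - a.total_vf_events,
                icer=ratio,
                classification=classify_wtp(ratio, wtp_lo, wtp_hi),
            ))
    return CEAResult(by_name, pairwise, wtp_lo, wtp_hi)
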