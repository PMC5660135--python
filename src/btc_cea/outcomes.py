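"""Base-case cost-effectiveness outcomes: ICER, net monetary benefit, verdict.

The incremental cost-effectiveness ratio compares the combination strategy
(GC) against monotherapy (G): ``ICER = dCost / dQALY`` with effects converted
from quality-adjusted life months by an exact division by 12. A strategy is
cost-effective when the ICER falls below the willingness-to-pay threshold, or
equivalently when the incremental net monetary benefit
``NMB = WTP * dQALY - dCost`` is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .markov import accrue, build_rewards, build_transition_matrix, run_cohort
from .parameters import ParameterSet

__all__ = ["ArmResult", "CEComparison", "arm_result", "base_case", "compare", "net_monetary_benefit"]


@dataclass
class ArmResult:
    arm: str
    total_cost: float  # yen, discounted
    total_effect: float  # quality-adjusted life months, discounted


@dataclass
class CEComparison:
    delta_cost: float
    delta_effect_qalm: float
    delta_effect_qaly: float
    icer: Optional[float]  # yen/QALY; None when the effect increment is zero
    status: str  # "icer" | "dominant" | "dominated" | "indifferent" | "tradeoff"
    nmb_at_wtp: float  # incremental NMB at the configured WTP
    cost_effective: bool
    wtp: float


def net_monetary_benefit(cost: float, effect_qaly: float, wtp: float) -> float:
    """``wtp * effect - cost``, in yen."""
    if wtp < 0:
        raise ValueError(f"willingness to pay must be nonnegative, got {wtp}")
    return wtp * effect_qaly - cost


def compare(treat: ArmResult, ref: ArmResult, wtp: float) -> CEComparison:
    """Incremental comparison of ``treat`` against ``ref``.

    The ICER is reported in yen per QALY. Quadrant handling: more effective
    and cheaper is "dominant", less effective and costlier "dominated",
    identical arms "indifferent"; less effective but cheaper is a "tradeoff"
    (the ICER then reads as savings per QALY forgone). The cost-effectiveness
    verdict is always the sign of the incremental net monetary benefit, which
    coincides with ICER < WTP whenever the effect gain is positive.
    """
    d_cost = treat.total_cost - ref.total_cost
    d_qalm = treat.total_effect - ref.total_effect
    d_qaly = d_qalm / 12.0
    nmb = net_monetary_benefit(d_cost, d_qaly, wtp)

    if d_qalm == 0.0:
        status = "indifferent" if d_cost == 0.0 else ("dominated" if d_cost > 0 else "dominant")
        icer = None
    else:
        icer = d_cost / d_qaly
        if d_qaly > 0:
            status = "icer" if d_cost > 0 else "dominant"
        else:
            status = "dominated" if d_cost >= 0 else "tradeoff"

    return CEComparison(
        delta_cost=d_cost,
        delta_effect_qalm=d_qalm,
        delta_effect_qaly=d_qaly,
        icer=icer,
        status=status,
        nmb_at_wtp=nmb,
        cost_effective=nmb > 0,
        wtp=wtp,
    )


def arm_result(params: ParameterSet, arm: str) -> ArmResult:
    """Run the cohort pipeline for one strategy and accrue discounted totals."""
    a = params.analysis
    ap = getattr(params, arm.lower())
    matrix = build_transition_matrix(
        ap.p_progress, ap.p_death, conditional=a.progression_conditional
    )
    n_cycles = a.horizon_months + 1 if a.half_cycle else a.horizon_months
    trace = run_cohort(matrix, n_cycles, arm=arm.lower())
    rewards = build_rewards(params, arm)
    cost, qalm = accrue(trace, rewards, a.monthly_discount_rate(), half_cycle=a.half_cycle)
    return ArmResult(arm=arm.lower(), total_cost=cost, total_effect=qalm)


def base_case(params: ParameterSet) -> tuple[ArmResult, ArmResult, CEComparison]:
    """Full deterministic pipeline: both arms plus their incremental comparison."""
    gc = arm_result(params, "gc")
    g = arm_result(params, "g")
    return gc, g, compare(gc, g, params.analysis.wtp_per_qaly)
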