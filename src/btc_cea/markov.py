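"""Three-state Markov cohort engine: no-progress, progress, death.

Monthly cycles. The cohort starts progression-free; progression is
irreversible and death is absorbing. Death is drawn with the same monthly
probability from both alive states, which makes the modeled survival curve
exactly geometric, ``S(k) = (1-p_death)^k`` — the property that lets the
model reproduce the trial's median overall survival and hazard ratio from
the derived monthly probabilities alone.

Two structures are supported for how progression and death combine in the
pre-progression state:

* competing (default): ``NP->P = p_progress``, ``NP->D = p_death`` — both
  risks drawn directly at their monthly probabilities;
* conditional: ``NP->P = (1-p_death) * p_progress`` — progression applies
  only to the month's survivors.

Both leave survival geometric; they differ only in progress-state occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "STATES",
    "CohortTrace",
    "StateRewards",
    "build_transition_matrix",
    "run_cohort",
    "build_rewards",
    "accrue",
    "survival_curve",
    "modeled_median_os",
    "modeled_hazard_ratio",
    "trace_to_frame",
]

STATES = ("no_progress", "progress", "death")

_ROW_TOL = 1e-12


def build_transition_matrix(
    p_progress: float, p_death: float, conditional: bool = False
) -> np.ndarray:
    """3x3 monthly transition matrix over (no_progress, progress, death).

    With ``conditional=False`` progression and death compete directly
    (requires ``p_progress + p_death <= 1``); with ``conditional=True``
    progression applies to death-survivors. Death is absorbing and there is
    no recovery from progression.
    """
    for name, p in (("p_progress", p_progress), ("p_death", p_death)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if conditional:
        row_np = [(1 - p_death) * (1 - p_progress), (1 - p_death) * p_progress, p_death]
    else:
        stay = 1.0 - p_progress - p_death
        if stay < -_ROW_TOL:
            raise ValueError(
                f"p_progress + p_death = {p_progress + p_death} exceeds 1; "
                "use conditional=True or rescale"
            )
        row_np = [max(stay, 0.0), p_progress, p_death]
    return np.array([row_np, [0.0, 1.0 - p_death, p_death], [0.0, 0.0, 1.0]])


@dataclass
class CohortTrace:
    """State-occupancy fractions per cycle (rows: cycle 0..len-1)."""

    occupancy: np.ndarray
    arm: str = ""

    def __len__(self) -> int:
        return self.occupancy.shape[0]


@dataclass
class StateRewards:
    """Per-state monthly cost (yen) and utility weight for one arm."""

    costs: np.ndarray
    utilities: np.ndarray
    arm: str = ""


def run_cohort(matrix: np.ndarray, horizon: int, init=(1.0, 0.0, 0.0), arm: str = "") -> CohortTrace:
    """Propagate the cohort: occupancy at cycle k is ``init @ matrix^k``,
    for k = 0..horizon-1."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (3, 3) or np.any(matrix < 0) or np.any(
        np.abs(matrix.sum(axis=1) - 1.0) > _ROW_TOL
    ):
        raise ValueError("transition matrix must be 3x3 row-stochastic")
    init = np.asarray(init, dtype=float)
    if abs(init.sum() - 1.0) > 1e-9:
        raise ValueError("initial occupancy must sum to 1")
    if horizon < 1:
        raise ValueError(f"horizon must be >= 1, got {horizon}")
    occ = np.empty((horizon, 3))
    occ[0] = init
    for k in range(1, horizon):
        occ[k] = occ[k - 1] @ matrix
    return CohortTrace(occupancy=occ, arm=arm)


def build_rewards(params: ParameterSet, arm: str) -> StateRewards:
    """State rewards for one strategy.

    Pre-progression months carry outpatient + inpatient + drug cost plus the
    expected G-CSF cost of adverse events, and a utility that mixes the
    adverse-event weight in proportion to the arm's AE probability. Progressed
    months carry the palliative-care cost at the progressed-state utility.
    Death carries nothing.
    """
    arm = arm.lower()
    if arm not in ("gc", "g"):
        raise ValueError(f"arm must be 'gc' or 'g', got {arm!r}")
    ap = getattr(params, arm)
    c, u = params.costs, params.utilities
    cost_np = c.outpatient + c.inpatient + ap.cost_drug + ap.p_ae * c.gcsf
    util_np = ap.p_ae * u.adverse_event + (1.0 - ap.p_ae) * u.no_progress
    return StateRewards(
        costs=np.array([cost_np, c.palliative, 0.0]),
        utilities=np.array([util_np, u.progress, 0.0]),
        arm=arm,
    )


def accrue(
    trace: CohortTrace,
    rewards: StateRewards,
    monthly_discount: float,
    half_cycle: bool = False,
) -> tuple[float, float]:
    """Discounted totals (cost in yen, effect in quality-adjusted life months).

    Rewards accrue at cycle start: ``sum_k (occ_k . reward) (1+d)^-k``. With
    ``half_cycle=True`` the first and last trace rows get weight 1/2
    (trapezoid rule); pass a trace one cycle longer than the horizon so the
    endpoint lands on cycle H.
    """
    if trace.arm and rewards.arm and trace.arm != rewards.arm:
        raise ValueError(f"trace arm {trace.arm!r} != rewards arm {rewards.arm!r}")
    n = len(trace)
    disc = (1.0 + monthly_discount) ** (-np.arange(n, dtype=float))
    weights = np.ones(n)
    if half_cycle:
        weights[0] = weights[-1] = 0.5
    w = weights * disc
    cost = float(w @ (trace.occupancy @ rewards.costs))
    qalm = float(w @ (trace.occupancy @ rewards.utilities))
    return cost, qalm


def survival_curve(trace: CohortTrace) -> np.ndarray:
    """Alive fraction per cycle: 1 minus death occupancy."""
    return 1.0 - trace.occupancy[:, 2]


def modeled_median_os(p_death: float) -> float:
    """Median overall survival (months) of the geometric modeled curve,
    continuously interpolated: ``ln(0.5) / ln(1-p_death)``."""
    if not 0.0 < p_death < 1.0:
        raise ValueError(f"p_death must lie strictly in (0, 1), got {p_death}")
    return math.log(0.5) / math.log(1.0 - p_death)


def modeled_hazard_ratio(p_death_treat: float, p_death_ref: float) -> float:
    """Hazard ratio implied by two monthly death probabilities: the ratio of
    the equivalent continuous hazards ``ln(1-p_t) / ln(1-p_r)``."""
    for name, p in (("treatment", p_death_treat), ("reference", p_death_ref)):
        if not 0.0 < p < 1.0:
            raise ValueError(f"{name} death probability must lie in (0, 1), got {p}")
    return math.log(1.0 - p_death_treat) / math.log(1.0 - p_death_ref)


def trace_to_frame(trace: CohortTrace, monthly_discount: float = 0.0) -> pd.DataFrame:
    """Trace as a tidy table: cycle, occupancies, alive, discount factor."""
    n = len(trace)
    return pd.DataFrame(
        {
            "cycle": np.arange(n),
            "no_progress": trace.occupancy[:, 0],
            "progress": trace.occupancy[:, 1],
            "death": trace.occupancy[:, 2],
            "alive": survival_curve(trace),
            "discount_factor": (1.0 + monthly_discount) ** (-np.arange(n, dtype=float)),
        }
    )
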