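"""Synthetic data: individual-level microsimulation and exponential trials.

Two independent oracles for the cohort engine:

* :func:`simulate_patients` walks individual patients through the same
  three-state chain with per-cycle categorical draws and accrues each
  patient's discounted cost and quality-adjusted life months under the same
  cycle-start convention as the cohort engine, so Monte Carlo means can be
  checked against the deterministic trace.
* :func:`generate_trial` emulates the source trial: per-patient exponential
  times to progression and death whose medians match the published trial
  medians, censored at the horizon. :func:`recover_probabilities` estimates
  the monthly transition probabilities back from such a trial
  (events / person-time, converted through ``p = 1 - exp(-r)``), closing the
  derivation loop median -> probability -> simulated data -> probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import StateRewards
from .parameters import rate_to_probability

__all__ = [
    "MicrosimResult",
    "SyntheticTrial",
    "RecoveredRates",
    "simulate_patients",
    "generate_trial",
    "recover_probabilities",
]


@dataclass
class MicrosimResult:
    """Per-patient trajectories (state index per cycle) and accrued rewards."""

    states: np.ndarray  # (n_patients, horizon) int8, 0=no_progress 1=progress 2=death
    cost: np.ndarray  # (n_patients,) discounted yen
    qalm: np.ndarray  # (n_patients,) discounted quality-adjusted life months
    arm: str = ""

    @property
    def n_patients(self) -> int:
        return self.states.shape[0]

    def occupancy(self) -> np.ndarray:
        """Empirical state-occupancy fractions per cycle, (horizon, 3)."""
        n, horizon = self.states.shape
        return np.stack([(self.states == s).mean(axis=0) for s in range(3)], axis=1)

    def to_frame(self) -> pd.DataFrame:
        n, horizon = self.states.shape
        return pd.DataFrame(
            {
                "patient": np.repeat(np.arange(n), horizon),
                "cycle": np.tile(np.arange(horizon), n),
                "state": self.states.ravel(),
            }
        )


def simulate_patients(
    matrix: np.ndarray,
    rewards: StateRewards,
    n: int,
    horizon: int,
    monthly_discount: float,
    seed: int | np.random.Generator = 0,
) -> MicrosimResult:
    """Walk ``n`` patients through the chain for ``horizon`` monthly cycles.

    Rewards accrue at cycle start for the state occupied that cycle, cycles
    0..horizon-1, discounted by ``(1+d)^-k`` — the cohort engine's convention,
    so sample means are directly comparable with :func:`~btc_cea.markov.accrue`.
    """
    if n < 1 or horizon < 1:
        raise ValueError("need n >= 1 and horizon >= 1")
    matrix = np.asarray(matrix, dtype=float)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cum = matrix.cumsum(axis=1)

    states = np.zeros((n, horizon), dtype=np.int8)
    current = np.zeros(n, dtype=np.int8)
    cost = np.zeros(n)
    qalm = np.zeros(n)
    for k in range(horizon):
        states[:, k] = current
        disc = (1.0 + monthly_discount) ** (-k)
        cost += disc * rewards.costs[current]
        qalm += disc * rewards.utilities[current]
        if k < horizon - 1:
            u = rng.random(n)
            # vectorized categorical draw via each row's cumulative probabilities
            current = (u[:, None] > cum[current]).sum(axis=1).astype(np.int8)
    return MicrosimResult(states=states, cost=cost, qalm=qalm, arm=rewards.arm)


@dataclass
class SyntheticTrial:
    """Per-patient exponential event times, censored at the horizon."""

    data: pd.DataFrame  # columns: patient, arm, t_prog, t_death, horizon
    horizon: float

    def to_frame(self) -> pd.DataFrame:
        out = self.data.copy()
        out["censored_death"] = out["t_death"] > self.horizon
        return out


def generate_trial(
    median_os: float,
    median_pfs: float,
    n_per_arm: int,
    horizon: float,
    seed: int | np.random.Generator = 0,
    arm: str = "g",
) -> SyntheticTrial:
    """Draw exponential times to death and progression with hazards
    ``ln2/median``, independently per patient, censored at ``horizon``."""
    if median_os <= 0 or median_pfs <= 0:
        raise ValueError("medians must be positive")
    if n_per_arm < 1:
        raise ValueError("n_per_arm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h_death = np.log(2.0) / median_os
    h_prog = np.log(2.0) / median_pfs
    data = pd.DataFrame(
        {
            "patient": np.arange(n_per_arm),
            "arm": arm,
            "t_prog": rng.exponential(1.0 / h_prog, n_per_arm),
            "t_death": rng.exponential(1.0 / h_death, n_per_arm),
        }
    )
    data["horizon"] = float(horizon)
    return SyntheticTrial(data=data, horizon=float(horizon))


@dataclass
class RecoveredRates:
    p_death: float
    p_death_se: float
    p_progress: float
    p_progress_se: float
    n_deaths: int
    n_progressions: int
    warning: str = ""


def recover_probabilities(trial: SyntheticTrial) -> RecoveredRates:
    """Estimate monthly transition probabilities from a synthetic trial.

    Hazards are the censored-exponential MLE, events divided by person-time
    (death: time to death or censoring; progression: time to the first of
    progression, death, censoring), then converted to monthly probabilities
    via ``p = 1 - exp(-r)``. Standard errors by the delta method from
    ``se(r) = r / sqrt(events)``.
    """
    t_death = trial.data["t_death"].to_numpy()
    t_prog = trial.data["t_prog"].to_numpy()
    h = trial.horizon

    obs_death = np.minimum(t_death, h)
    deaths = int(np.sum(t_death <= h))
    at_risk_prog = np.minimum(t_prog, np.minimum(t_death, h))
    progs = int(np.sum((t_prog < t_death) & (t_prog <= h)))

    warning = ""

    def estimate(events: int, person_time: float) -> tuple[float, float]:
        nonlocal warning
        if events == 0:
            warning = "zero events; estimate is 0"
            return 0.0, 0.0
        r = events / person_time
        se_r = r / np.sqrt(events)
        return rate_to_probability(r), float(np.exp(-r) * se_r)

    p_d, se_d = estimate(deaths, float(obs_death.sum()))
    p_p, se_p = estimate(progs, float(at_risk_prog.sum()))
    return RecoveredRates(
        p_death=p_d,
        p_death_se=se_d,
        p_progress=p_p,
        p_progress_se=se_p,
        n_deaths=deaths,
        n_progressions=progs,
        warning=warning,
    )
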