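"""Probabilistic sensitivity analysis: Monte Carlo draws and the CEAC.

Every parameter with a distribution spec is drawn jointly (independently
across parameters), the full deterministic pipeline runs per draw, and the
cost-effectiveness acceptability curve reports, for each willingness-to-pay
value, the fraction of draws in which the combination strategy has positive
incremental net monetary benefit. Sampled utilities are clamped at 1.0 by
default (a gamma has unbounded support; weights above perfect health are not
meaningful).

Reproducibility: one root seed is split into per-parameter substreams via
``numpy.random.SeedSequence.spawn`` in sorted parameter order, so adding or
reordering spec entries does not silently reshuffle every other parameter's
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import base_case
from .parameters import DistributionSpec, ParameterSet, make_sampler

__all__ = ["PsaResult", "CeacCurve", "sample_parameter_set", "draw_matrix", "run_psa", "ceac", "default_wtp_grid"]

_UTILITY_PARAMS = ("utilities.no_progress", "utilities.progress", "utilities.adverse_event")


@dataclass
class PsaResult:
    seed: int
    n_draws: int
    delta_cost: np.ndarray  # yen, per draw
    delta_effect_qaly: np.ndarray  # QALY, per draw
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)  # draws per parameter

    def nmb(self, wtp: float) -> np.ndarray:
        return wtp * self.delta_effect_qaly - self.delta_cost

    def prob_cost_effective(self, wtp: float) -> float:
        return float(np.mean(self.nmb(wtp) > 0))


@dataclass
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "probability": self.probability})


def _clamp_utilities(values: dict[str, float], base: ParameterSet) -> dict[str, float]:
    if base.analysis.clamp_utilities:
        for key in _UTILITY_PARAMS:
            if key in values:
                values[key] = min(values[key], 1.0)
    return values


def sample_parameter_set(
    specs: list[DistributionSpec], base: ParameterSet, rng: np.random.Generator
) -> ParameterSet:
    """One joint draw: each uncertain parameter replaced by a sample from its
    distribution, fixed parameters untouched."""
    values = {spec.param: float(make_sampler(spec, rng)(1)[0]) for spec in specs}
    return base.with_values(_clamp_utilities(values, base))


def draw_matrix(
    specs: list[DistributionSpec], base: ParameterSet, seed: int, n: int
) -> pd.DataFrame:
    """n joint draws, one column per parameter, per-parameter substreams."""
    root = np.random.SeedSequence(seed)
    ordered = sorted(specs, key=lambda s: s.param)
    children = root.spawn(len(ordered))
    cols = {}
    for spec, child in zip(ordered, children):
        cols[spec.param] = make_sampler(spec, np.random.default_rng(child))(n)
    frame = pd.DataFrame(cols)
    if base.analysis.clamp_utilities:
        for key in _UTILITY_PARAMS:
            if key in frame:
                frame[key] = frame[key].clip(upper=1.0)
    return frame


def run_psa(
    base: ParameterSet, specs: list[DistributionSpec], n: int = 10_000, seed: int = 0
) -> PsaResult:
    """Seeded Monte Carlo PSA: per draw, rebuild the parameter set and run the
    full matrices -> traces -> accrual -> increments pipeline."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    samples = draw_matrix(specs, base, seed, n)
    d_cost = np.empty(n)
    d_qaly = np.empty(n)
    records = samples.to_dict("records") if not samples.empty else [{}] * n
    for i, row in enumerate(records):
        params = base.with_values(row) if row else base
        _, _, cmp_ = base_case(params)
        d_cost[i] = cmp_.delta_cost
        d_qaly[i] = cmp_.delta_effect_qaly
    return PsaResult(seed=seed, n_draws=n, delta_cost=d_cost, delta_effect_qaly=d_qaly, samples=samples)


def default_wtp_grid() -> np.ndarray:
    """0 to 20 million yen per QALY in 250,000-yen steps."""
    return np.arange(0, 20_000_001, 250_000, dtype=float)


def ceac(result: PsaResult, wtp_grid=None) -> CeacCurve:
    """Cost-effectiveness acceptability curve over a willingness-to-pay grid."""
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("wtp grid must be nonempty")
    # fraction of draws with wtp * dE - dC > 0, vectorized over the grid
    nmb = grid[:, None] * result.delta_effect_qaly[None, :] - result.delta_cost[None, :]
    return CeacCurve(wtp=grid, probability=(nmb > 0).mean(axis=1))
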