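"""Model parameters: conversions, uncertainty distributions, and config loading.

The decision model compares gemcitabine+cisplatin (GC) against gemcitabine
alone (G) for advanced biliary tract cancer over monthly cycles. All inputs —
monthly transition probabilities derived from trial medians, adverse-event
probabilities, EQ-5D utility weights, and monthly costs in yen — live in a
:class:`ParameterSet` loaded from a YAML/JSON config. Each uncertain input
additionally carries a :class:`DistributionSpec` (beta for probabilities,
gamma for utilities and surveyed costs, triangular for tariff-based costs)
used by the probabilistic sensitivity analysis.
"""

from __future__ import annotations

import math
from typing import Callable, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ConfigurationError",
    "DistributionSpec",
    "ArmParams",
    "SharedCosts",
    "Utilities",
    "AnalysisSettings",
    "ParameterSet",
    "rate_to_probability",
    "probability_to_rate",
    "median_to_monthly_probability",
    "beta_sd_from_mean_n",
    "triangular_bounds",
    "triangular_density",
    "make_sampler",
    "monthly_discount",
    "load_parameters",
    "round_yen",
]


class ConfigurationError(ValueError):
    """A config file is malformed, incomplete, or holds out-of-range values."""


# ---------------------------------------------------------------------------
# rate <-> probability conversions
# ---------------------------------------------------------------------------

def rate_to_probability(r: float, t: float = 1.0) -> float:
    """Convert a constant hazard ``r`` (per month) over ``t`` months to a
    transition probability: ``p = 1 - exp(-r t)``."""
    if r < 0 or t < 0:
        raise ValueError(f"rate and time must be nonnegative, got r={r}, t={t}")
    return 1.0 - math.exp(-r * t)


def probability_to_rate(p: float, t: float = 1.0) -> float:
    """Inverse of :func:`rate_to_probability`: ``r = -ln(1-p)/t``."""
    if not 0.0 <= p < 1.0:
        raise ValueError(f"probability must lie in [0, 1), got {p}")
    if t <= 0:
        raise ValueError(f"time must be positive, got {t}")
    return -math.log1p(-p) / t


def median_to_monthly_probability(median_months: float) -> float:
    """Monthly transition probability implied by an exponential survival curve
    with the given median: hazard ``ln 2 / median``, so
    ``p = 1 - exp(-ln2/median)``.

    This is how the trial medians (overall survival 11.2/7.7 months,
    progression-free survival 5.8/3.7 months) become the model's monthly
    mortality and progression probabilities.
    """
    if median_months <= 0:
        raise ValueError(f"median must be positive, got {median_months}")
    return rate_to_probability(math.log(2.0) / median_months, 1.0)


def beta_sd_from_mean_n(
    mean: float, n: int, variant: Literal["eq3", "binomial"] = "binomial"
) -> float:
    """Standard deviation of a beta built from ``r = mean*n`` events in ``n``.

    ``variant="eq3"`` is the beta distribution's own SD,
    ``sqrt(r(n-r) / (n^2 (n+1)))``; ``variant="binomial"`` is the binomial
    proportion SD ``sqrt(mean(1-mean)/n)``. The two disagree by the factor
    ``sqrt(n/(n+1))`` and published parameter tables are not always consistent
    about which they print, hence both are available.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie in (0, 1), got {mean}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    r = mean * n
    if variant == "eq3":
        return math.sqrt(r * (n - r) / (n**2 * (n + 1)))
    if variant == "binomial":
        return math.sqrt(mean * (1.0 - mean) / n)
    raise ValueError(f"unknown variant {variant!r}")


def round_yen(x: float) -> int:
    """Round to the nearest yen, halves away from zero."""
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def triangular_bounds(mode: float) -> tuple[int, int]:
    """±10 % triangular bounds around a most-likely cost, rounded to the yen."""
    if mode <= 0:
        raise ValueError(f"mode must be positive, got {mode}")
    return round_yen(0.9 * mode), round_yen(1.1 * mode)


def triangular_density(x: float, a: float, m: float, b: float) -> float:
    """Density of the triangular distribution with support [a, b] and mode m."""
    if not (a <= m <= b) or a >= b:
        raise ValueError(f"need a <= m <= b with a < b, got a={a}, m={m}, b={b}")
    if x < a or x > b:
        return 0.0
    if x < m:
        return 2.0 * (x - a) / ((b - a) * (m - a))
    if x == m:
        return 2.0 / (b - a)
    return 2.0 * (b - x) / ((b - a) * (b - m))


def monthly_discount(annual: float) -> float:
    """Compound conversion of an annual discount rate to a monthly one:
    ``(1+annual)^(1/12) - 1``."""
    if annual < -1.0:
        raise ValueError(f"annual discount below -100% is meaningless: {annual}")
    return (1.0 + annual) ** (1.0 / 12.0) - 1.0


# ---------------------------------------------------------------------------
# Distribution specs and samplers
# ---------------------------------------------------------------------------

class DistributionSpec(BaseModel):
    """Declarative description of one uncertain parameter.

    ``param`` is the dotted id of the :class:`ParameterSet` entry the draw
    replaces (e.g. ``"gc.p_death"``, ``"costs.inpatient"``).

    Beta specs may carry both a printed ``sd`` and an effective sample size
    ``n``; ``beta_by`` picks which parameterization the sampler uses:
    ``"counts"`` builds Beta(r, n-r) with r = mean*n (a beta constructed
    directly from event counts), ``"moments"`` matches (mean, sd).
    """

    model_config = ConfigDict(extra="forbid")

    param: str
    kind: Literal["beta", "gamma", "triangular", "fixed"]
    mean: Optional[float] = None
    sd: Optional[float] = Field(default=None, ge=0.0)
    n: Optional[int] = Field(default=None, ge=1)
    beta_by: Literal["counts", "moments"] = "counts"
    minimum: Optional[float] = None
    mode: Optional[float] = None
    maximum: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        k = self.kind
        if k == "beta":
            if self.mean is None or not 0.0 < self.mean < 1.0:
                raise ValueError(f"{self.param}: beta mean must lie in (0,1)")
            if self.beta_by == "counts" and self.n is None:
                raise ValueError(f"{self.param}: beta_by='counts' needs n")
            if self.beta_by == "moments" and not self.sd:
                raise ValueError(f"{self.param}: beta_by='moments' needs sd > 0")
        elif k == "gamma":
            if self.mean is None or self.mean <= 0 or not self.sd:
                raise ValueError(f"{self.param}: gamma needs mean > 0 and sd > 0")
        elif k == "triangular":
            if None in (self.minimum, self.mode, self.maximum):
                raise ValueError(f"{self.param}: triangular needs minimum/mode/maximum")
            if not (self.minimum <= self.mode <= self.maximum) or self.minimum >= self.maximum:
                raise ValueError(
                    f"{self.param}: need minimum <= mode <= maximum with minimum < maximum"
                )
        elif k == "fixed":
            if self.mean is None:
                raise ValueError(f"{self.param}: fixed needs mean")
        return self


def beta_moment_params(mean: float, sd: float) -> tuple[float, float]:
    """Method-of-moments (alpha, beta) for a beta with the given mean and sd."""
    nu = mean * (1.0 - mean) / sd**2 - 1.0
    if nu <= 0:
        raise ConfigurationError(
            f"sd {sd} too large for a beta with mean {mean} (implied nu={nu:.4g} <= 0)"
        )
    return mean * nu, (1.0 - mean) * nu


def make_sampler(
    spec: DistributionSpec, rng: np.random.Generator
) -> Callable[[int], np.ndarray]:
    """Build a vectorized sampler ``f(size) -> ndarray`` for one spec.

    beta: Beta(r, n-r) from counts, or moment-matched to (mean, sd);
    gamma: shape = (mean/sd)^2, scale = sd^2/mean;
    triangular: on (minimum, mode, maximum); fixed: the constant mean.
    """
    if spec.kind == "fixed":
        value = float(spec.mean)
        return lambda size: np.full(size, value)
    if spec.kind == "beta":
        if spec.beta_by == "counts":
            r = spec.mean * spec.n
            a, b = r, spec.n - r
        else:
            a, b = beta_moment_params(spec.mean, spec.sd)
        return lambda size: rng.beta(a, b, size)
    if spec.kind == "gamma":
        shape = (spec.mean / spec.sd) ** 2
        scale = spec.sd**2 / spec.mean
        return lambda size: rng.gamma(shape, scale, size)
    # triangular
    lo, md, hi = float(spec.minimum), float(spec.mode), float(spec.maximum)
    return lambda size: rng.triangular(lo, md, hi, size)


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------

class ArmParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    p_progress: float = Field(ge=0.0, le=1.0)
    p_death: float = Field(ge=0.0, le=1.0)
    p_ae: float = Field(ge=0.0, le=1.0)
    cost_drug: float = Field(ge=0.0)


class SharedCosts(BaseModel):
    model_config = ConfigDict(extra="forbid")
    outpatient: float = Field(ge=0.0)
    inpatient: float = Field(ge=0.0)
    palliative: float = Field(ge=0.0)
    gcsf: float = Field(ge=0.0)


class Utilities(BaseModel):
    model_config = ConfigDict(extra="forbid")
    no_progress: float = Field(ge=0.0, le=1.0)
    progress: float = Field(ge=0.0, le=1.0)
    adverse_event: float = Field(ge=0.0, le=1.0)


class AnalysisSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    horizon_months: int = Field(ge=1)
    discount_annual: float = Field(ge=0.0)
    wtp_per_qaly: float = Field(ge=0.0)
    half_cycle: bool = False
    # progression drawn in competition with death (NP->P = p_progress) when
    # False is "conditional": NP->P = (1-p_death)*p_progress.
    progression_conditional: bool = False
    clamp_utilities: bool = True
    # optional direct override of the monthly discount (used by the DSA,
    # whose published range is on the monthly scale)
    discount_monthly: Optional[float] = None

    def monthly_discount_rate(self) -> float:
        if self.discount_monthly is not None:
            return self.discount_monthly
        return monthly_discount(self.discount_annual)


class ParameterSet(BaseModel):
    """Complete deterministic model input for both strategies."""

    model_config = ConfigDict(extra="forbid")

    gc: ArmParams
    g: ArmParams
    costs: SharedCosts
    utilities: Utilities
    analysis: AnalysisSettings

    # -- dotted-id access, shared by the DSA and PSA -----------------------
    _SECTIONS = {"gc", "g", "costs", "utilities", "analysis"}

    def get_value(self, param_id: str) -> float:
        section, _, field = param_id.partition(".")
        if section not in self._SECTIONS or not field:
            raise KeyError(f"unknown parameter id {param_id!r}")
        obj = getattr(self, section)
        if not hasattr(obj, field):
            raise KeyError(f"unknown parameter id {param_id!r}")
        return getattr(obj, field)

    def with_value(self, param_id: str, value: float) -> "ParameterSet":
        """Return a copy with one parameter replaced (validation re-runs)."""
        self.get_value(param_id)  # raises KeyError on unknown ids
        section, _, field = param_id.partition(".")
        data = self.model_dump()
        data[section][field] = value
        try:
            return ParameterSet.model_validate(data)
        except ValueError as exc:
            raise ConfigurationError(f"invalid value for {param_id}: {exc}") from exc

    def with_values(self, updates: dict[str, float]) -> "ParameterSet":
        data = self.model_dump()
        for param_id, value in updates.items():
            self.get_value(param_id)
            section, _, field = param_id.partition(".")
            data[section][field] = value
        try:
            return ParameterSet.model_validate(data)
        except ValueError as exc:
            raise ConfigurationError(f"invalid sampled/updated values: {exc}") from exc


def load_parameters(path) -> tuple[ParameterSet, list[DistributionSpec]]:
    """Load a YAML/JSON config into a validated ParameterSet plus the list of
    distribution specs for the probabilistic analysis.

    Unknown keys are rejected; every distribution's ``param`` must resolve to
    an existing parameter. Errors name the offending key.
    """
    import yaml

    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except OSError as exc:
        raise ConfigurationError(f"cannot read config {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config {path} must be a mapping")

    dist_raw = raw.pop("distributions", [])
    arms = raw.pop("arms", None)  # config nests the two strategies under "arms"
    if isinstance(arms, dict):
        raw.update(arms)
    try:
        params = ParameterSet.model_validate(raw)
    except ValueError as exc:
        raise ConfigurationError(f"invalid config {path}: {exc}") from exc

    specs = []
    for entry in dist_raw:
        try:
            spec = DistributionSpec.model_validate(entry)
        except ValueError as exc:
            raise ConfigurationError(f"invalid distribution entry {entry!r}: {exc}") from exc
        try:
            params.get_value(spec.param)
        except KeyError:
            raise ConfigurationError(
                f"distribution {spec.param!r} does not match any model parameter"
            ) from None
        specs.append(spec)
    return params, specs
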