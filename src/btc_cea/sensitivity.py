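"""One-way deterministic sensitivity analysis and tornado ordering.

Each uncertain parameter is swept to the low and high end of its published
range with everything else held at base case, the full pipeline re-run, and
the induced ICER span recorded. Entries sorted by span descending give the
tornado diagram; the robustness check flags any bound at which the verdict
flips (incremental NMB turns positive, i.e. the combination becomes
cost-effective at the configured willingness to pay).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .outcomes import base_case
from .parameters import ConfigurationError, ParameterSet

__all__ = ["DsaRange", "TornadoEntry", "one_way", "tornado", "load_ranges", "tornado_to_frame"]


@dataclass
class DsaRange:
    param: str
    low: float
    high: float
    label: str = ""

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError(f"{self.param}: low {self.low} > high {self.high}")


@dataclass
class TornadoEntry:
    param: str
    label: str
    low: float
    high: float
    icer_low: Optional[float]  # ICER with the parameter at its low bound
    icer_high: Optional[float]
    span: float
    flips_verdict: bool  # combination becomes cost-effective at either bound


def _icer_at(base: ParameterSet, param: str, value: float):
    try:
        params = base.with_value(param, value)
    except KeyError:
        raise ConfigurationError(f"unknown parameter id {param!r} in DSA range") from None
    _, _, cmp_ = base_case(params)
    return cmp_.icer, cmp_.cost_effective


def one_way(base: ParameterSet, rng: DsaRange) -> TornadoEntry:
    """Re-run the pipeline with one parameter at each bound of its range."""
    icer_lo, ce_lo = _icer_at(base, rng.param, rng.low)
    icer_hi, ce_hi = _icer_at(base, rng.param, rng.high)
    if icer_lo is None or icer_hi is None:
        span = float("nan")
    else:
        span = abs(icer_hi - icer_lo)
    return TornadoEntry(
        param=rng.param,
        label=rng.label or rng.param,
        low=rng.low,
        high=rng.high,
        icer_low=icer_lo,
        icer_high=icer_hi,
        span=span,
        flips_verdict=ce_lo or ce_hi,
    )


def tornado(base: ParameterSet, ranges: list[DsaRange]) -> list[TornadoEntry]:
    """One-way DSA over all ranges, sorted by ICER span descending."""
    if not ranges:
        raise ValueError("ranges must be nonempty")
    entries = [one_way(base, r) for r in ranges]
    entries.sort(key=lambda e: e.span, reverse=True)
    return entries


def load_ranges(path) -> list[DsaRange]:
    """Load DSA ranges from a YAML list of {param, low, high, label} entries."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list) or not raw:
        raise ConfigurationError(f"ranges file {path} must hold a nonempty list")
    out = []
    for entry in raw:
        try:
            out.append(
                DsaRange(
                    param=entry["param"],
                    low=float(entry["low"]),
                    high=float(entry["high"]),
                    label=str(entry.get("label", "")),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigurationError(f"invalid range entry {entry!r}: {exc}") from exc
    return out


def tornado_to_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "param": [e.param for e in entries],
            "label": [e.label for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "span": [e.span for e in entries],
            "flips_verdict": [e.flips_verdict for e in entries],
        }
    )
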