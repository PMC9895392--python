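"""Estimate mean and SD from median/quantile summaries.

Implements the quantile-based estimators of Luo et al. (sample mean) and
Wan et al. (sample SD) for three reporting scenarios:

* S1 — minimum, median, maximum;
* S2 — first quartile, median, third quartile;
* S3 — all five numbers.

The mean uses Luo's optimal weightings; the SD divides the observed spread
by twice the expected normal quantile for the given sample size (S3 averages
the two spread-based estimates).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum

from scipy.stats import norm

from .exceptions import ValidationError
from .studies import ArmSummary

__all__ = ["Scenario", "QuantileSummary", "estimate_mean", "estimate_sd", "convert_summary"]


class Scenario(str, Enum):
    S1 = "S1"  # (min, median, max)
    S2 = "S2"  # (q1, median, q3)
    S3 = "S3"  # all five


@dataclass(frozen=True)
class QuantileSummary:
    """Quantile-style summary of one arm, as reported by an article."""

    n: int
    median: float
    q1: float | None = None
    q3: float | None = None
    minimum: float | None = None
    maximum: float | None = None
    scenario: Scenario | None = None  # inferred from present fields if None

    def __post_init__(self) -> None:
        if not (isinstance(self.n, int) and self.n >= 1):
            raise ValidationError(f"n must be a positive integer, got {self.n!r}")
        scenario = self.scenario or self._infer_scenario()
        object.__setattr__(self, "scenario", Scenario(scenario))
        self._check_fields()
        self._check_ordering()

    def _infer_scenario(self) -> Scenario:
        has_q = self.q1 is not None and self.q3 is not None
        has_ext = self.minimum is not None and self.maximum is not None
        if has_q and has_ext:
            return Scenario.S3
        if has_q:
            return Scenario.S2
        if has_ext:
            return Scenario.S1
        raise ValidationError("need quartiles and/or extremes alongside the median")

    def _check_fields(self) -> None:
        need: dict[Scenario, tuple[str, ...]] = {
            Scenario.S1: ("minimum", "maximum"),
            Scenario.S2: ("q1", "q3"),
            Scenario.S3: ("minimum", "q1", "q3", "maximum"),
        }
        missing = [f for f in need[self.scenario] if getattr(self, f) is None]
        if missing:
            raise ValidationError(
                f"scenario {self.scenario.value} requires field(s): {', '.join(missing)}"
            )

    def _check_ordering(self) -> None:
        order = [
            v
            for v in (self.minimum, self.q1, self.median, self.q3, self.maximum)
            if v is not None
        ]
        if any(a > b for a, b in zip(order, order[1:])):
            raise ValidationError(f"quantiles out of order: {order}")


def estimate_mean(q: QuantileSummary) -> float:
    """Estimate the sample mean from a quantile summary (Luo weights).

    The scenario-specific weights always sum to 1, so symmetric summaries
    return the median exactly.
    """
    n = q.n
    if q.scenario is Scenario.S1:
        w = 4.0 / (4.0 + n**0.75)
        return w * (q.minimum + q.maximum) / 2.0 + (1.0 - w) * q.median
    if q.scenario is Scenario.S2:
        w = 0.7 + 0.39 / n
        return w * (q.q1 + q.q3) / 2.0 + (1.0 - w) * q.median
    w1 = 2.2 / (2.2 + n**0.75)
    w2 = 0.7 - 0.72 / n**0.55
    return (
        w1 * (q.minimum + q.maximum) / 2.0
        + w2 * (q.q1 + q.q3) / 2.0
        + (1.0 - w1 - w2) * q.median
    )


def _range_sd(spread: float, prob: float) -> float:
    return spread / (2.0 * norm.ppf(prob))


def estimate_sd(q: QuantileSummary) -> float:
    """Estimate the sample SD from a quantile summary (Wan formulas).

    A degenerate spread (q3 == q1, or max == min) yields 0 with a warning.
    """
    n = q.n
    if q.scenario is Scenario.S1:
        out = _range_sd(q.maximum - q.minimum, (n - 0.375) / (n + 0.25))
    elif q.scenario is Scenario.S2:
        out = _range_sd(q.q3 - q.q1, (0.75 * n - 0.125) / (n + 0.25))
    else:
        out = 0.5 * (
            _range_sd(q.maximum - q.minimum, (n - 0.375) / (n + 0.25))
            + _range_sd(q.q3 - q.q1, (0.75 * n - 0.125) / (n + 0.25))
        )
    if out == 0.0:
        warnings.warn("degenerate spread: SD estimated as 0", stacklevel=2)
    return out


def convert_summary(q: QuantileSummary) -> ArmSummary:
    """Convert a quantile summary into an (n, mean, sd) arm summary."""
    mean = estimate_mean(q)
    sd = estimate_sd(q)
    assert math.isfinite(mean) and sd >= 0.0
    return ArmSummary(n=q.n, mean=mean, sd=sd)
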