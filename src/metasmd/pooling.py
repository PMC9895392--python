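"""Inverse-variance pooling: fixed effect, DerSimonian-Laird random effects,
heterogeneity statistics, and raw-mean pooling for reference intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .effects import Z_CRIT, EffectEstimate
from .exceptions import InsufficientStudiesError, ValidationError
from .studies import ArmSummary

__all__ = ["PoolModel", "PoolResult", "fixed_effect", "dersimonian_laird", "pool_raw_means"]


class PoolModel(str, Enum):
    FIXED = "fixed"
    RANDOM_DL = "random_DL"


@dataclass(frozen=True)
class PoolResult:
    """A pooled effect with heterogeneity statistics.

    ``weights`` are the per-study weights normalized to sum to 1, in input
    order.  ``q_stat``/``i_squared``/``tau_squared`` are always computed on
    the fixed-effect (1/v) weights; for the fixed model tau_squared is 0 by
    construction.  ``i_squared`` is in percent, clamped to [0, 100].
    """

    k: int
    model: PoolModel
    pooled: float
    se: float
    q_stat: float
    tau_squared: float
    weights: tuple[float, ...]
    study_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be >= 1")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValidationError(f"se must be positive and finite, got {self.se!r}")

    @property
    def df(self) -> int:
        return self.k - 1

    @property
    def ci_low(self) -> float:
        return self.pooled - Z_CRIT * self.se

    @property
    def ci_high(self) -> float:
        return self.pooled + Z_CRIT * self.se

    @property
    def i_squared(self) -> float:
        if self.q_stat <= 0.0:
            return 0.0
        return max(0.0, (self.q_stat - self.df) / self.q_stat) * 100.0


def _check_effects(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if len(effects) == 0:
        raise InsufficientStudiesError("need at least one effect estimate")
    theta = np.array([e.smd for e in effects], dtype=float)
    var = np.array([e.variance for e in effects], dtype=float)
    if np.any(var <= 0.0):
        raise ValidationError("all effect variances must be positive")
    return theta, var


def _pool(theta: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    wsum = weights.sum()
    return float((weights * theta).sum() / wsum), float(1.0 / math.sqrt(wsum))


def fixed_effect(effects: Sequence[EffectEstimate]) -> PoolResult:
    """Fixed-effect (inverse-variance) pooling with Cochran's Q."""
    theta, var = _check_effects(effects)
    w = 1.0 / var
    pooled, se = _pool(theta, w)
    q = float((w * (theta - pooled) ** 2).sum())
    return PoolResult(
        k=len(effects),
        model=PoolModel.FIXED,
        pooled=pooled,
        se=se,
        q_stat=q,
        tau_squared=0.0,
        weights=tuple(w / w.sum()),
        study_ids=tuple(e.study_id for e in effects),
    )


def dersimonian_laird(effects: Sequence[EffectEstimate]) -> PoolResult:
    """DerSimonian-Laird random-effects pooling.

    The between-study variance is the method-of-moments estimate
    ``tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w)))`` on the
    fixed-effect weights ``w = 1/v``; random-effects weights are
    ``1/(v + tau^2)``.  With a single study tau^2 is 0 and the result
    equals the fixed-effect (and the study's own) estimate.
    """
    theta, var = _check_effects(effects)
    fe = fixed_effect(effects)
    k = len(effects)
    tau2 = 0.0
    if k >= 2:
        w = 1.0 / var
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (fe.q_stat - (k - 1)) / denom)
    w_star = 1.0 / (var + tau2)
    pooled, se = _pool(theta, w_star)
    return PoolResult(
        k=k,
        model=PoolModel.RANDOM_DL,
        pooled=pooled,
        se=se,
        q_stat=fe.q_stat,
        tau_squared=tau2,
        weights=tuple(w_star / w_star.sum()),
        study_ids=fe.study_ids,
    )


def pool_raw_means(
    arms: Sequence[ArmSummary],
    units: Sequence[str] | None = None,
    model: PoolModel | str = PoolModel.RANDOM_DL,
) -> PoolResult:
    """Pool raw arm means by inverse variance; the pooled 95% CI is the
    "reference interval" for the underlying level.

    Each arm's mean enters as the estimate with variance sd^2/n.  Mixed
    units trigger a warning but pooling proceeds; interpreting the result
    is then the caller's responsibility.
    """
    model = PoolModel(model)
    if len(arms) == 0:
        raise InsufficientStudiesError("need at least one arm")
    if any(a.sd <= 0 for a in arms):
        raise ValidationError("all arm SDs must be positive to pool raw means")
    if units is not None and len(set(units)) > 1:
        warnings.warn(f"pooling arms with mixed units: {sorted(set(units))}", stacklevel=2)
    effects = [
        EffectEstimate(
            study_id=f"arm{i}", smd=a.mean, variance=a.sd**2 / a.n, method="cohen"
        )
        for i, a in enumerate(arms)
    ]
    if model is PoolModel.FIXED:
        return fixed_effect(effects)
    return dersimonian_laird(effects)
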