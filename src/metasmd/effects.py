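"""Per-study standardized mean differences with analytic variances and CIs.

Sign convention: case minus control.  Confidence intervals use the normal
approximation with z = 1.96 throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .exceptions import DegenerateStudyError, ValidationError
from .studies import ArmSummary, StudyCollection

__all__ = ["SmdMethod", "EffectEstimate", "pooled_sd", "smd", "effects_from_collection", "Z_CRIT"]

Z_CRIT = 1.96


class SmdMethod(str, Enum):
    COHEN = "cohen"
    HEDGES = "hedges"


@dataclass(frozen=True)
class EffectEstimate:
    """A study-level standardized mean difference with its variance and CI."""

    study_id: str
    smd: float
    variance: float
    method: SmdMethod

    def __post_init__(self) -> None:
        object.__setattr__(self, "method", SmdMethod(self.method))
        if not (self.variance > 0 and math.isfinite(self.variance)):
            raise ValidationError(f"variance must be positive and finite, got {self.variance!r}")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)

    @property
    def ci_low(self) -> float:
        return self.smd - Z_CRIT * self.se

    @property
    def ci_high(self) -> float:
        return self.smd + Z_CRIT * self.se


def pooled_sd(case: ArmSummary, control: ArmSummary) -> float:
    """Pooled within-group SD: sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)).

    Returns 0 when both arm SDs are 0; such a study has no defined SMD and
    must be rejected by the caller.
    """
    df = case.n + control.n - 2
    if df < 1:
        raise ValidationError(f"total degrees of freedom must be >= 1, got {df}")
    num = (case.n - 1) * case.sd**2 + (control.n - 1) * control.sd**2
    return math.sqrt(num / df)


def smd(
    case: ArmSummary,
    control: ArmSummary,
    method: SmdMethod | str = SmdMethod.COHEN,
    study_id: str = "",
) -> EffectEstimate:
    """Standardized mean difference (case minus control) for one study.

    Parameters
    ----------
    case, control : ArmSummary
        The two arms; both need n >= 2.
    method : {"cohen", "hedges"}
        Cohen's d, or Hedges' g = J*d with the small-sample correction
        J = 1 - 3/(4(n1+n2)-9).

    Variances are the standard large-sample forms:
    ``(n1+n2)/(n1*n2) + d^2/(2(n1+n2))`` for Cohen's d and
    ``(n1+n2)/(n1*n2) + g^2/(2(n1+n2-3.94))`` for Hedges' g.

    Raises
    ------
    DegenerateStudyError
        If the pooled SD is 0 (no within-group variability).
    """
    method = SmdMethod(method)
    if case.n < 2 or control.n < 2:
        raise ValidationError(f"both arms need n >= 2 (study {study_id or '<unnamed>'})")
    sp = pooled_sd(case, control)
    if sp == 0.0:
        raise DegenerateStudyError(
            f"study {study_id or '<unnamed>'}: pooled SD is 0, SMD undefined"
        )
    n1, n2 = case.n, control.n
    ntot = n1 + n2
    d = (case.mean - control.mean) / sp
    if method is SmdMethod.COHEN:
        est = d
        var = ntot / (n1 * n2) + est**2 / (2.0 * ntot)
    else:
        j = 1.0 - 3.0 / (4.0 * ntot - 9.0)
        est = j * d
        var = ntot / (n1 * n2) + est**2 / (2.0 * (ntot - 3.94))
    return EffectEstimate(study_id=study_id, smd=est, variance=var, method=method)


def effects_from_collection(
    collection: StudyCollection, method: SmdMethod | str = SmdMethod.COHEN
) -> list[EffectEstimate]:
    """Compute one SMD per study record, in collection order."""
    return [smd(r.case, r.control, method=method, study_id=r.study_id) for r in collection]
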