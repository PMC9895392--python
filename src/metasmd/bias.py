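"""Publication-bias diagnostics and sensitivity analyses.

Begg's rank-correlation test correlates standardized effect deviates with
their variances (Kendall score, normal approximation, optional continuity
correction).  Egger's test regresses the standardized effect on precision
and tests the intercept against 0.  Sensitivity analyses re-pool after
omitting one study at a time, or after restricting to studies that
excluded confounding conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate, SmdMethod, effects_from_collection
from .exceptions import InsufficientStudiesError, ValidationError
from .pooling import PoolModel, PoolResult, dersimonian_laird, fixed_effect
from .studies import ExcludesConfounders, StudyCollection, filter_studies

__all__ = [
    "BiasMethod",
    "BiasTestResult",
    "LeaveOneOutRow",
    "beggs_test",
    "eggers_test",
    "leave_one_out",
    "restricted_analysis",
]


class BiasMethod(str, Enum):
    BEGG = "begg"
    EGGER = "egger"


@dataclass(frozen=True)
class BiasTestResult:
    """Two-sided publication-bias test result.

    ``statistic`` is the Kendall score S for Begg and the regression
    intercept for Egger; ``test_value`` is the corresponding z or t.
    """

    method: BiasMethod
    statistic: float
    test_value: float
    p_value: float
    df: int | None = None
    continuity_corrected: bool | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"p_value out of [0, 1]: {self.p_value!r}")


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_study_id: str
    result: PoolResult


def beggs_test(
    effects: Sequence[EffectEstimate], continuity_correction: bool = True
) -> BiasTestResult:
    """Begg-Mazumdar rank-correlation test for funnel-plot asymmetry.

    Per study the deviate ``u_i = (theta_i - theta_fixed) / sqrt(v_i - 1/sum(w))``
    is ranked against ``v_i``; S counts concordant minus discordant pairs
    (ties excluded), and ``z = (|S| - c) / sqrt(k(k-1)(2k+5)/18)`` with
    c = 1 under the continuity correction (default).
    """
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Begg's test needs k >= 3, got {k}")
    theta = np.array([e.smd for e in effects])
    var = np.array([e.variance for e in effects])
    fe = fixed_effect(effects)
    vstar = var - fe.se**2  # variance of theta_i - theta_fixed
    if np.any(vstar <= 0.0):
        warnings.warn(
            "non-positive deviate variance; using absolute value", stacklevel=2
        )
        vstar = np.abs(vstar)
    u = (theta - fe.pooled) / np.sqrt(vstar)

    s = 0
    for i, j in combinations(range(k), 2):
        du, dv = u[i] - u[j], var[i] - var[j]
        if du == 0.0 or dv == 0.0:
            continue  # tied pair contributes nothing
        s += 1 if (du > 0) == (dv > 0) else -1

    sd_s = math.sqrt(k * (k - 1) * (2 * k + 5) / 18.0)
    c = 1.0 if continuity_correction else 0.0
    z = max(0.0, abs(s) - c) / sd_s
    p = 2.0 * stats.norm.sf(z)
    return BiasTestResult(
        method=BiasMethod.BEGG,
        statistic=float(s),
        test_value=float(z),
        p_value=float(min(1.0, p)),
        continuity_corrected=continuity_correction,
    )


def eggers_test(effects: Sequence[EffectEstimate]) -> BiasTestResult:
    """Egger's regression test: OLS of theta_i/se_i on 1/se_i, t-test on the
    intercept with k - 2 degrees of freedom."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError(f"Egger's test needs k >= 3, got {k}")
    se = np.array([e.se for e in effects])
    y = np.array([e.smd for e in effects]) / se
    x = 1.0 / se
    if np.ptp(x) == 0.0:
        raise ValidationError("all precisions identical: Egger design is singular")
    fit = stats.linregress(x, y)
    df = k - 2
    if fit.intercept_stderr == 0.0:
        # perfect fit: intercept is exact, test degenerates
        t = 0.0 if fit.intercept == 0.0 else math.copysign(math.inf, fit.intercept)
        p = 1.0 if fit.intercept == 0.0 else 0.0
    else:
        t = fit.intercept / fit.intercept_stderr
        p = 2.0 * stats.t.sf(abs(t), df)
    return BiasTestResult(
        method=BiasMethod.EGGER,
        statistic=float(fit.intercept),
        test_value=float(t),
        p_value=float(p),
        df=df,
    )


def leave_one_out(
    effects: Sequence[EffectEstimate], model: PoolModel | str = PoolModel.RANDOM_DL
) -> list[LeaveOneOutRow]:
    """Re-pool omitting each study in turn; rows are in input order."""
    model = PoolModel(model)
    if len(effects) < 2:
        raise InsufficientStudiesError("leave-one-out needs k >= 2")
    pool = dersimonian_laird if model is PoolModel.RANDOM_DL else fixed_effect
    rows = []
    for i, omitted in enumerate(effects):
        subset = [e for j, e in enumerate(effects) if j != i]
        rows.append(LeaveOneOutRow(omitted_study_id=omitted.study_id, result=pool(subset)))
    return rows


def restricted_analysis(
    collection: StudyCollection,
    method: SmdMethod | str = SmdMethod.COHEN,
    model: PoolModel | str = PoolModel.RANDOM_DL,
) -> PoolResult:
    """Pool only the studies that excluded confounding conditions."""
    restricted = filter_studies(collection, excludes_confounders=ExcludesConfounders.YES)
    if len(restricted) == 0:
        raise InsufficientStudiesError("no studies with excludes_confounders=yes")
    effects = effects_from_collection(restricted, method=method)
    model = PoolModel(model)
    if model is PoolModel.FIXED:
        return fixed_effect(effects)
    return dersimonian_laird(effects)
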