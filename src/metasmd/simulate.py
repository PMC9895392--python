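"""Synthetic study collections with random-effects structure.

Per retained study a true standardized effect is drawn around a grand mean
with between-study variance tau^2, arm-level normal data are drawn and
summarized to (n, mean, SD), and an optional selective-publication
mechanism discards non-significant studies with a given probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .bias import beggs_test, eggers_test
from .effects import SmdMethod, effects_from_collection
from .exceptions import ValidationError
from .pooling import dersimonian_laird
from .studies import ArmSummary, Level, StudyCollection, StudyRecord, Timing

__all__ = ["SimConfig", "simulate_collection", "operating_characteristics"]


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic meta-analysis.

    ``suppress_prob`` is the probability of discarding a study whose
    two-sided per-study effect test has p >= 0.05 (0 disables the
    publication-bias mechanism); generation continues until ``k`` studies
    are retained.
    """

    k: int = 10
    mu: float = 0.5
    tau_squared: float = 0.0
    n_case_range: tuple[int, int] = (20, 100)
    n_control_range: tuple[int, int] = (20, 100)
    sigma_range: tuple[float, float] = (0.5, 2.0)
    control_mean_range: tuple[float, float] = (5.0, 15.0)
    suppress_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")
        if self.tau_squared < 0:
            raise ValidationError(f"tau_squared must be >= 0, got {self.tau_squared}")
        if not 0.0 <= self.suppress_prob <= 1.0:
            raise ValidationError(f"suppress_prob must be in [0, 1], got {self.suppress_prob}")
        for name in ("n_case_range", "n_control_range"):
            lo, hi = getattr(self, name)
            if not (2 <= lo <= hi):
                raise ValidationError(f"{name} must satisfy 2 <= lo <= hi, got {(lo, hi)}")
        for name in ("sigma_range", "control_mean_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValidationError(f"{name} must satisfy lo <= hi, got {(lo, hi)}")
        if self.sigma_range[0] <= 0:
            raise ValidationError("sigma_range must be positive")


def _draw_study(rng: np.random.Generator, config: SimConfig, idx: int) -> StudyRecord:
    delta = rng.normal(config.mu, np.sqrt(config.tau_squared))
    n1 = int(rng.integers(config.n_case_range[0], config.n_case_range[1] + 1))
    n2 = int(rng.integers(config.n_control_range[0], config.n_control_range[1] + 1))
    sigma = rng.uniform(*config.sigma_range)
    m2 = rng.uniform(*config.control_mean_range)
    m1 = m2 + delta * sigma
    case_data = rng.normal(m1, sigma, size=n1)
    control_data = rng.normal(m2, sigma, size=n2)
    return StudyRecord(
        study_id=f"SIM{idx:04d}",
        timing=Timing.LATE,
        level=Level.PROTEIN,
        case=ArmSummary(n=n1, mean=float(case_data.mean()), sd=float(case_data.std(ddof=1))),
        control=ArmSummary(
            n=n2, mean=float(control_data.mean()), sd=float(control_data.std(ddof=1))
        ),
    )


def _is_suppressed(rng: np.random.Generator, record: StudyRecord, prob: float) -> bool:
    from scipy import stats

    from .effects import smd

    if prob == 0.0:
        return False
    eff = smd(record.case, record.control, study_id=record.study_id)
    p = 2.0 * stats.norm.sf(abs(eff.smd / eff.se))
    return p >= 0.05 and rng.uniform() < prob


def simulate_collection(config: SimConfig) -> StudyCollection:
    """Generate a seeded synthetic StudyCollection with exactly config.k studies."""
    rng = np.random.default_rng(config.seed)
    records: list[StudyRecord] = []
    idx = 0
    while len(records) < config.k:
        idx += 1
        rec = _draw_study(rng, config, idx)
        if _is_suppressed(rng, rec, config.suppress_prob):
            continue
        records.append(rec)
    return StudyCollection(records=records, provenance=f"simulated:seed={config.seed}")


@dataclass(frozen=True)
class OperatingCharacteristics:
    reps: int
    alpha: float
    begg_rejection_rate: float
    egger_rejection_rate: float
    mean_tau_squared: float
    ci_coverage_mu: float
    mc_se: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        return {
            "reps": self.reps,
            "alpha": self.alpha,
            "begg_rejection_rate": self.begg_rejection_rate,
            "egger_rejection_rate": self.egger_rejection_rate,
            "mean_tau_squared": self.mean_tau_squared,
            "ci_coverage_mu": self.ci_coverage_mu,
            "mc_se": dict(self.mc_se),
        }


def operating_characteristics(
    config: SimConfig, reps: int, alpha: float = 0.05
) -> OperatingCharacteristics:
    """Empirical operating characteristics of the full pipeline.

    Runs ``reps`` independent replicates of simulate -> SMD -> DL pooling ->
    Begg/Egger, and returns the rejection rates at ``alpha``, the mean
    estimated tau^2, and the DL 95% CI coverage of the true mu, each with a
    binomial/empirical Monte-Carlo standard error.
    """
    if reps < 100:
        raise ValidationError(f"reps must be >= 100, got {reps}")
    seed_seq = np.random.SeedSequence(config.seed)
    begg_rej = egger_rej = covered = 0
    tau2s = np.empty(reps)
    for r, child in enumerate(seed_seq.spawn(reps)):
        cfg = SimConfig(
            **{
                **{f: getattr(config, f) for f in config.__dataclass_fields__},
                "seed": int(child.generate_state(1)[0]),
            }
        )
        coll = simulate_collection(cfg)
        effects = effects_from_collection(coll, method=SmdMethod.COHEN)
        pool = dersimonian_laird(effects)
        tau2s[r] = pool.tau_squared
        if pool.ci_low <= config.mu <= pool.ci_high:
            covered += 1
        if beggs_test(effects).p_value < alpha:
            begg_rej += 1
        if eggers_test(effects).p_value < alpha:
            egger_rej += 1

    def binom_se(p: float) -> float:
        return float(np.sqrt(p * (1.0 - p) / reps))

    rates = {
        "begg_rejection_rate": begg_rej / reps,
        "egger_rejection_rate": egger_rej / reps,
        "ci_coverage_mu": covered / reps,
    }
    return OperatingCharacteristics(
        reps=reps,
        alpha=alpha,
        mean_tau_squared=float(tau2s.mean()),
        mc_se={
            **{k: binom_se(v) for k, v in rates.items()},
            "mean_tau_squared": float(tau2s.std(ddof=1) / np.sqrt(reps)),
        },
        **rates,
    )
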