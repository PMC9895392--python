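"""One-shot reproduction of every published analysis from the packaged
fixtures, plus forest-table rendering and JSON serialization helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

from .bias import (
    BiasTestResult,
    LeaveOneOutRow,
    beggs_test,
    eggers_test,
    leave_one_out,
    restricted_analysis,
)
from .effects import EffectEstimate, SmdMethod, effects_from_collection
from .exceptions import ValidationError
from .pooling import PoolModel, PoolResult, dersimonian_laird
from .studies import Level, Timing, load_gdf15_fixture

__all__ = [
    "PUBLISHED_POOLED",
    "PUBLISHED_TALLIES",
    "PaperReport",
    "reproduce_paper",
    "render_forest_table",
    "pool_result_to_dict",
    "bias_result_to_dict",
]

# Published pooled SMD (95% CI) triples, as printed in the source analysis.
PUBLISHED_POOLED: dict[str, tuple[float, float, float]] = {
    "mrna_late": (0.48, 0.14, 0.83),
    "mrna_middle": (-0.27, -1.26, 0.73),
    "protein_late": (0.82, 0.32, 1.33),
    "protein_middle": (0.53, 0.04, 1.02),
    "restricted_mrna_late": (0.61, 0.09, 1.13),
    "restricted_protein_late": (0.57, 0.18, 0.96),
    "restricted_protein_middle": (0.39, -0.12, 0.91),
}

# Published (case, control) sample-size tallies.
PUBLISHED_TALLIES: dict[str, tuple[int, int]] = {
    "overall": (789, 1202),
    "mrna_late": (142, 313),
    "protein_late": (228, 459),
    "protein_middle": (412, 421),
    "restricted_mrna_late": (95, 267),
}

_STRATA: dict[str, tuple[Level, Timing]] = {
    "mrna_late": (Level.MRNA, Timing.LATE),
    "mrna_middle": (Level.MRNA, Timing.MIDDLE),
    "protein_late": (Level.PROTEIN, Timing.LATE),
    "protein_middle": (Level.PROTEIN, Timing.MIDDLE),
}


@dataclass
class PaperReport:
    """Computed results for every published analysis, with deviations."""

    tallies: dict[str, tuple[int, int]] = field(default_factory=dict)
    pooled: dict[str, PoolResult] = field(default_factory=dict)
    restricted: dict[str, PoolResult] = field(default_factory=dict)
    loo: dict[str, list[LeaveOneOutRow]] = field(default_factory=dict)
    bias: dict[str, dict[str, BiasTestResult]] = field(default_factory=dict)
    comparison: list[dict[str, Any]] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "tallies": {k: list(v) for k, v in self.tallies.items()},
            "pooled": {k: pool_result_to_dict(v) for k, v in self.pooled.items()},
            "restricted": {k: pool_result_to_dict(v) for k, v in self.restricted.items()},
            "leave_one_out": {
                k: [
                    {"omitted": row.omitted_study_id, **pool_result_to_dict(row.result)}
                    for row in rows
                ]
                for k, rows in self.loo.items()
            },
            "bias": {
                k: {m: bias_result_to_dict(r) for m, r in tests.items()}
                for k, tests in self.bias.items()
            },
            "comparison": list(self.comparison),
        }


def reproduce_paper(method: SmdMethod | str = SmdMethod.COHEN) -> PaperReport:
    """Run the full fixture pipeline: SMDs, DL pooling in all four strata,
    the three restricted analyses, leave-one-out, and both bias tests.

    Deterministic: repeated calls return identical results.
    """
    report = PaperReport()
    collections = {name: load_gdf15_fixture(lv, tm) for name, (lv, tm) in _STRATA.items()}

    for name, coll in collections.items():
        report.tallies[name] = (coll.total_case_n, coll.total_control_n)
        effects = effects_from_collection(coll, method=method)
        pool = dersimonian_laird(effects)
        report.pooled[name] = pool
        if len(effects) >= 2:
            report.loo[name] = leave_one_out(effects, model=PoolModel.RANDOM_DL)
        if len(effects) >= 3:
            report.bias[name] = {
                "begg": beggs_test(effects),
                "egger": eggers_test(effects),
            }

    report.tallies["overall"] = (
        sum(report.tallies[n][0] for n in _STRATA),
        sum(report.tallies[n][1] for n in _STRATA),
    )
    for name in ("mrna_late", "protein_late", "protein_middle"):
        restricted = restricted_analysis(collections[name], method=method)
        report.restricted[f"restricted_{name}"] = restricted

    from .studies import ExcludesConfounders, filter_studies

    restr_mrna = filter_studies(
        collections["mrna_late"], excludes_confounders=ExcludesConfounders.YES
    )
    report.tallies["restricted_mrna_late"] = (
        restr_mrna.total_case_n,
        restr_mrna.total_control_n,
    )

    for name, (pub_est, pub_lo, pub_hi) in PUBLISHED_POOLED.items():
        result = report.restricted.get(name) or report.pooled[name]
        for quantity, computed, published in (
            ("smd", result.pooled, pub_est),
            ("ci_low", result.ci_low, pub_lo),
            ("ci_high", result.ci_high, pub_hi),
        ):
            report.comparison.append(
                {
                    "analysis": name,
                    "quantity": quantity,
                    "computed": round(computed, 4),
                    "published": published,
                    "abs_deviation": round(abs(computed - published), 4),
                }
            )
    return report


def render_forest_table(
    result: PoolResult, effects: Sequence[EffectEstimate]
) -> list[dict[str, Any]]:
    """Tabular forest-plot data: one row per study plus a pooled row.

    Weights are the pooling weights expressed in percent; they sum to 100
    within rounding.  Raises if ``effects`` are not the effects that were
    pooled into ``result``.
    """
    if tuple(e.study_id for e in effects) != result.study_ids:
        raise ValidationError("effects do not match the studies pooled in result")
    rows: list[dict[str, Any]] = []
    for eff, weight in zip(effects, result.weights):
        rows.append(
            {
                "study_id": eff.study_id,
                "estimate": eff.smd,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "weight_percent": 100.0 * weight,
            }
        )
    rows.append(
        {
            "study_id": f"pooled ({result.model.value})",
            "estimate": result.pooled,
            "ci_low": result.ci_low,
            "ci_high": result.ci_high,
            "weight_percent": 100.0,
        }
    )
    return rows


def pool_result_to_dict(result: PoolResult) -> dict[str, Any]:
    return {
        "k": result.k,
        "model": result.model.value,
        "pooled": result.pooled,
        "se": result.se,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "q_stat": result.q_stat,
        "df": result.df,
        "i_squared": result.i_squared,
        "tau_squared": result.tau_squared,
        "weights": list(result.weights),
        "study_ids": list(result.study_ids),
    }


def bias_result_to_dict(result: BiasTestResult) -> dict[str, Any]:
    out = {
        "method": result.method.value,
        "statistic": result.statistic,
        "test_value": result.test_value,
        "p_value": result.p_value,
    }
    if result.df is not None:
        out["df"] = result.df
    if result.continuity_corrected is not None:
        out["continuity_corrected"] = result.continuity_corrected
    return out
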