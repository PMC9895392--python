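import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from metasmd import (
    EffectEstimate,
    PoolModel,
    beggs_test,
    dersimonian_laird,
    eggers_test,
    fixed_effect,
    leave_one_out,
    restricted_analysis,
)
from metasmd.exceptions import InsufficientStudiesError, ValidationError


def make_effects(pairs):
    return [
        EffectEstimate(study_id=f"s{i}", smd=t, variance=v, method="cohen")
        for i, (t, v) in enumerate(pairs)
    ]


def begg_oracle(effects, continuity=True):
    """Exhaustive pair-counting oracle, recomputed from first principles."""
    k = len(effects)
    theta = np.array([e.smd for e in effects])
    var = np.array([e.variance for e in effects])
    w = 1.0 / var
    pooled = (w * theta).sum() / w.sum()
    u = (theta - pooled) / np.sqrt(var - 1.0 / w.sum())
    s = 0
    for i, j in combinations(range(k), 2):
        s += int(np.sign(u[i] - u[j]) * np.sign(var[i] - var[j]))
    z = max(0.0, abs(s) - (1.0 if continuity else 0.0)) / math.sqrt(
        k * (k - 1) * (2 * k + 5) / 18.0
    )
    return s, min(1.0, 2.0 * stats.norm.sf(z))


class TestBegg:
    def test_perfectly_concordant_construction(self):
        # u and v sorted identically: S = C(5,2) = 10
        pairs = [(0.0, 0.05), (0.5, 0.1), (1.2, 0.2), (2.1, 0.4), (3.5, 0.8)]
        res = beggs_test(make_effects(pairs))
        assert res.statistic == 10.0

    def test_fixture_strata_not_significant(
        self, mrna_late_effects, protein_late_effects, protein_middle_effects
    ):
        for effects in (mrna_late_effects, protein_late_effects, protein_middle_effects):
            assert beggs_test(effects).p_value > 0.05

    def test_k6_against_pair_counting_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(20):
            pairs = list(zip(rng.normal(0, 1, 6), rng.uniform(0.02, 0.5, 6)))
            res = beggs_test(make_effects(pairs))
            s, p = begg_oracle(make_effects(pairs))
            assert res.statistic == s
            assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_continuity_flag(self):
        pairs = [(0.0, 0.05), (0.5, 0.1), (1.2, 0.2), (2.1, 0.4), (3.5, 0.8)]
        corrected = beggs_test(make_effects(pairs), continuity_correction=True)
        raw = beggs_test(make_effects(pairs), continuity_correction=False)
        assert raw.test_value > corrected.test_value
        assert raw.p_value < corrected.p_value

    def test_scale_transform_invariance(self):
        # v -> c*v with theta -> sqrt(c)*theta preserves deviates and v-order
        rng = np.random.default_rng(3)
        pairs = list(zip(rng.normal(0, 1, 8), rng.uniform(0.02, 0.5, 8)))
        base = beggs_test(make_effects(pairs))
        c = 7.3
        scaled = beggs_test(
            make_effects([(t * math.sqrt(c), v * c) for t, v in pairs])
        )
        assert scaled.statistic == base.statistic
        assert scaled.p_value == pytest.approx(base.p_value, abs=1e-12)

    def test_too_few_studies(self):
        with pytest.raises(InsufficientStudiesError):
            beggs_test(make_effects([(0.1, 0.1), (0.2, 0.2)]))


class TestEgger:
    def test_null_construction_not_significant(self):
        rng = np.random.default_rng(12)
        se = rng.uniform(0.1, 0.5, size=20)
        theta = 0.4 + rng.normal(0, 1, size=20) * se  # effect independent of precision
        res = eggers_test(make_effects(zip(theta, se**2)))
        assert res.p_value > 0.05

    def test_exact_common_effect_gives_zero_intercept(self):
        pairs = [(0.7, v) for v in (0.04, 0.09, 0.16, 0.25)]
        res = eggers_test(make_effects(pairs))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_k5_closed_form_oracle(self):
        # frozen from an independent least-squares computation
        se = [0.1, 0.2, 0.3, 0.4, 0.5]
        theta = [0.30, 0.45, 0.20, 0.65, 0.10]
        res = eggers_test(make_effects([(t, s**2) for t, s in zip(theta, se)]))
        assert res.statistic == pytest.approx(0.18327613516367514, abs=1e-10)
        assert res.test_value == pytest.approx(0.31718680311457187, abs=1e-10)
        assert res.p_value == pytest.approx(0.7718947970828166, abs=1e-10)
        assert res.df == 3

    def test_fixture_strata_not_significant(
        self, mrna_late_effects, protein_late_effects, protein_middle_effects
    ):
        for effects in (mrna_late_effects, protein_late_effects, protein_middle_effects):
            assert eggers_test(effects).p_value > 0.05

    def test_identical_precisions_singular(self):
        with pytest.raises(ValidationError, match="singular"):
            eggers_test(make_effects([(0.1, 0.04), (0.5, 0.04), (0.9, 0.04)]))

    def test_too_few_studies(self):
        with pytest.raises(InsufficientStudiesError):
            eggers_test(make_effects([(0.1, 0.1), (0.2, 0.2)]))


class TestLeaveOneOut:
    def test_k2_reduces_to_remaining_study(self):
        effects = make_effects([(0.2, 0.04), (0.8, 0.09)])
        rows = leave_one_out(effects)
        assert [r.omitted_study_id for r in rows] == ["s0", "s1"]
        assert rows[0].result.pooled == pytest.approx(0.8)
        assert rows[0].result.ci_low == pytest.approx(effects[1].ci_low)
        assert rows[1].result.pooled == pytest.approx(0.2)

    def test_compositional_oracle_k4(self):
        rng = np.random.default_rng(5)
        effects = make_effects(zip(rng.normal(0, 1, 4), rng.uniform(0.02, 0.4, 4)))
        rows = leave_one_out(effects, model=PoolModel.RANDOM_DL)
        for i, row in enumerate(rows):
            subset = [e for j, e in enumerate(effects) if j != i]
            direct = dersimonian_laird(subset)
            assert row.result == direct  # bit-identical
            assert row.result.k == len(effects) - 1

    def test_fixed_model_variant(self):
        effects = make_effects([(0.2, 0.04), (0.5, 0.09), (0.8, 0.25)])
        rows = leave_one_out(effects, model=PoolModel.FIXED)
        assert rows[0].result == fixed_effect(effects[1:])

    def test_mrna_late_mostly_positive(self, mrna_late_effects):
        rows = leave_one_out(mrna_late_effects)
        assert len(rows) == 12
        positive = sum(1 for r in rows if r.result.pooled > 0)
        assert positive >= 10  # direction basically stable

    def test_too_few_studies(self):
        with pytest.raises(InsufficientStudiesError):
            leave_one_out(make_effects([(0.1, 0.1)]))


class TestRestrictedAnalysis:
    def test_mrna_late(self, mrna_late):
        res = restricted_analysis(mrna_late)
        assert res.k == 5
        assert res.pooled == pytest.approx(0.61, abs=0.02)
        assert res.ci_low == pytest.approx(0.09, abs=0.03)
        assert res.ci_high == pytest.approx(1.13, abs=0.03)

    def test_protein_late(self, protein_late):
        res = restricted_analysis(protein_late)
        assert res.k == 3
        assert res.pooled == pytest.approx(0.57, abs=0.02)

    def test_protein_middle(self, protein_middle):
        res = restricted_analysis(protein_middle)
        assert res.k == 2
        assert res.pooled == pytest.approx(0.39, abs=0.02)
        assert res.ci_low == pytest.approx(-0.12, abs=0.03)
        assert res.ci_high == pytest.approx(0.91, abs=0.03)

    def test_empty_restriction_rejected(self, mrna_middle):
        from metasmd import StudyCollection, filter_studies

        none_flagged = filter_studies(mrna_middle, excludes_confounders="no")
        with pytest.raises(InsufficientStudiesError):
            restricted_analysis(StudyCollection(records=none_flagged.records))
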