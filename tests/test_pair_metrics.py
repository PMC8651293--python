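"""Pairwise replication-success criteria."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from repliscore import (
    EffectEstimate,
    EffectScale,
    DirectionLabel,
    HeterogeneityConfig,
    Interpretation,
    InvalidInputError,
    PairRecord,
    Reporting,
    SMDEstimate,
    Tristate,
    criteria_vector,
    es_comparison,
    expected_significance,
    p_orig,
    pooled_fixed_effect,
    prediction_interval,
    same_direction,
    significance_agreement,
)
from repliscore.pair_metrics import ci_inclusion

from conftest import make_pair

TAU0 = HeterogeneityConfig(0.0)


class TestSameDirection:
    def test_matching_signs_succeed(self):
        assert same_direction(make_pair(2.0, 0.5, 0.5, 0.3)) == Tristate.SUCCESS

    def test_opposite_signs_fail(self):
        assert same_direction(make_pair(2.0, 0.5, -0.1, 0.3)) == Tristate.FAILURE

    def test_null_originals_not_assessed(self):
        pair = make_pair(2.0, 0.5, 2.0, 0.5, interpretation=Interpretation.NULL)
        assert same_direction(pair) == Tristate.NOT_APPLICABLE

    def test_nil_replication_estimate_fails(self):
        assert same_direction(make_pair(2.0, 0.5, 0.0, 0.3)) == Tristate.FAILURE

    def test_image_only_pair_scored_from_labels(self):
        pair = PairRecord(
            paper_id="p", experiment_id="e", effect_id="f", outcome_id="o",
            original=EffectEstimate(
                scale=EffectScale.IMAGE_ONLY, direction_label=DirectionLabel.POSITIVE
            ),
            replication=EffectEstimate(
                scale=EffectScale.COHENS_D, estimate=0.7, se=0.2
            ),
            reporting=Reporting.IMAGE,
        )
        assert same_direction(pair) == Tristate.SUCCESS


class TestSignificanceAgreement:
    def test_significant_same_direction_succeeds(self):
        pair = make_pair(2.0, 0.5, 1.0, 0.2)  # rep z = 5
        assert significance_agreement(pair) == Tristate.SUCCESS

    def test_significant_opposite_direction_fails(self):
        pair = make_pair(2.0, 0.5, -1.0, 0.2)
        assert significance_agreement(pair) == Tristate.FAILURE

    def test_null_original_stays_null(self):
        pair = make_pair(0.2, 0.5, 0.3, 0.4, interpretation=Interpretation.NULL)
        assert significance_agreement(pair) == Tristate.SUCCESS

    def test_null_original_becoming_significant_fails(self):
        pair = make_pair(0.2, 0.5, 1.5, 0.2, interpretation=Interpretation.NULL)
        assert significance_agreement(pair) == Tristate.FAILURE

    def test_boundary_p_is_failure_for_positive_originals(self):
        # p exactly alpha is not "p < alpha"
        pair = PairRecord(
            paper_id="p", experiment_id="e", effect_id="f", outcome_id="o",
            original=EffectEstimate(scale=EffectScale.COHENS_D, estimate=1.0, se=0.3),
            replication=EffectEstimate(
                scale=EffectScale.COHENS_D, estimate=1.0, se=0.3, p_value=0.05
            ),
        )
        assert significance_agreement(pair) == Tristate.FAILURE

    def test_native_p_overrides_smd_p(self):
        # recorded native p-value wins even when normal theory disagrees
        pair = PairRecord(
            paper_id="p", experiment_id="e", effect_id="f", outcome_id="o",
            original=EffectEstimate(scale=EffectScale.COHENS_D, estimate=1.0, se=0.3),
            replication=EffectEstimate(
                scale=EffectScale.COHENS_D, estimate=2.0, se=0.2, p_value=0.30
            ),
        )
        assert significance_agreement(pair) == Tristate.FAILURE


class TestCiInclusion:
    def test_point_at_center_succeeds(self):
        holder = SMDEstimate(smd=0.43, se=0.2)
        assert ci_inclusion(0.43, holder) == Tristate.SUCCESS

    def test_distant_point_fails(self):
        holder = SMDEstimate(smd=0.43, se=0.20)
        assert ci_inclusion(2.96, holder) == Tristate.FAILURE

    def test_boundary_point_counts_as_success(self):
        holder = SMDEstimate(smd=1.0, se=0.5)
        z = stats.norm.ppf(0.975)
        assert ci_inclusion(1.0 + z * 0.5, holder) == Tristate.SUCCESS


class TestPOrig:
    def test_identical_estimates_give_one(self):
        a = SMDEstimate(smd=1.3, se=0.4)
        assert p_orig(a, a, TAU0) == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        o = SMDEstimate(smd=2.0, se=0.5)
        r = SMDEstimate(smd=0.5, se=0.3)
        assert p_orig(o, r, TAU0) == pytest.approx(0.0101, abs=2e-4)
        assert p_orig(o, r, HeterogeneityConfig(0.21)) == pytest.approx(0.0155, abs=3e-4)

    @given(
        d=st.floats(0.0, 4.0),
        se_o=st.floats(0.05, 2.0),
        se_r=st.floats(0.05, 2.0),
        tau=st.floats(0.0, 1.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_bounds_and_monotonicity_in_tau(self, d, se_o, se_r, tau):
        o = SMDEstimate(smd=1.0, se=se_o)
        r = SMDEstimate(smd=1.0 + d, se=se_r)
        p0 = p_orig(o, r, HeterogeneityConfig(0.0))
        pt = p_orig(o, r, HeterogeneityConfig(tau))
        assert 0.0 <= p0 <= 1.0
        assert pt >= p0 - 1e-12

    def test_decreasing_in_estimate_gap(self):
        o = SMDEstimate(smd=0.0, se=0.3)
        gaps = [0.1, 0.5, 1.0, 2.0, 4.0]
        ps = [p_orig(o, SMDEstimate(smd=g, se=0.3), TAU0) for g in gaps]
        assert all(b < a for a, b in zip(ps, ps[1:]))

    def test_uniform_under_shared_true_effect(self, rng):
        """Under a common population effect and tau=0, p_orig ~ Uniform(0,1)."""
        n = 10000
        se_o = rng.uniform(0.2, 0.8, n)
        se_r = rng.uniform(0.2, 0.8, n)
        true = rng.normal(1.0, 0.5, n)
        est_o = rng.normal(true, se_o)
        est_r = rng.normal(true, se_r)
        ps = np.array(
            [
                p_orig(SMDEstimate(smd=o, se=so), SMDEstimate(smd=r, se=sr), TAU0)
                for o, so, r, sr in zip(est_o, se_o, est_r, se_r)
            ]
        )
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPredictionInterval:
    def test_hand_evaluated_example(self):
        low, high = prediction_interval(SMDEstimate(smd=2.0, se=0.5), 0.3, TAU0)
        assert low == pytest.approx(0.857, abs=2e-3)
        assert high == pytest.approx(3.143, abs=2e-3)

    def test_equivalence_with_p_orig_on_random_pairs(self, rng):
        """pi_success(95%) <=> p_orig > 0.05, exactly, on 10,000 pairs."""
        disagreements = 0
        for _ in range(10000):
            o = SMDEstimate(smd=rng.normal(0, 2), se=rng.uniform(0.05, 1.5))
            r = SMDEstimate(smd=rng.normal(0, 2), se=rng.uniform(0.05, 1.5))
            low, high = prediction_interval(o, r.se, TAU0, 0.95)
            inside = low <= r.smd <= high
            if inside != (p_orig(o, r, TAU0) > 0.05):
                disagreements += 1
        assert disagreements == 0

    def test_widens_with_tau(self):
        o = SMDEstimate(smd=1.0, se=0.4)
        l0, h0 = prediction_interval(o, 0.3, HeterogeneityConfig(0.0))
        l1, h1 = prediction_interval(o, 0.3, HeterogeneityConfig(0.21))
        assert l1 < l0 and h1 > h0


class TestExpectedSignificance:
    def test_hand_evaluated_null_case(self):
        o = SMDEstimate(smd=1e-12, se=1.0)
        p = expected_significance(o, 1.0, TAU0)
        z = stats.norm.ppf(0.975)
        assert p == pytest.approx(stats.norm.sf(z / math.sqrt(2.0)), abs=1e-6)
        assert p == pytest.approx(0.0831, abs=5e-4)

    def test_limit_of_huge_effects(self):
        assert expected_significance(SMDEstimate(smd=50.0, se=1.0), 1.0, TAU0) > 0.999

    def test_matches_monte_carlo_rejection_rate(self, rng):
        """Closed form within 0.005 of simulation for 20 random settings."""
        z = stats.norm.ppf(0.975)
        for _ in range(20):
            theta = rng.normal(0, 2)
            se_o = rng.uniform(0.1, 1.0)
            se_r = rng.uniform(0.1, 1.0)
            analytic = expected_significance(
                SMDEstimate(smd=theta, se=se_o), se_r, TAU0
            )
            draws = rng.normal(theta, math.sqrt(se_o**2 + se_r**2), 100000)
            if theta >= 0:
                mc = np.mean(draws / se_r > z)
            else:
                mc = np.mean(draws / se_r < -z)
            assert analytic == pytest.approx(mc, abs=0.005)

    def test_mirrored_for_negative_originals(self):
        pos = expected_significance(SMDEstimate(smd=1.2, se=0.5), 0.4, TAU0)
        neg = expected_significance(SMDEstimate(smd=-1.2, se=0.5), 0.4, TAU0)
        assert pos == pytest.approx(neg, abs=1e-12)


class TestEsComparison:
    def test_shrunken_effect_fails(self):
        assert es_comparison(make_pair(2.96, 0.5, 0.43, 0.3)) == Tristate.FAILURE

    def test_tie_counts_as_success(self):
        assert es_comparison(make_pair(1.0, 0.5, 1.0, 0.3)) == Tristate.SUCCESS

    def test_measured_along_original_direction(self):
        # original negative: a more-negative replication is "at least as large"
        assert es_comparison(make_pair(-1.0, 0.5, -2.0, 0.3)) == Tristate.SUCCESS

    def test_null_originals_not_assessed(self):
        pair = make_pair(0.2, 0.5, 0.1, 0.3, interpretation=Interpretation.NULL)
        assert es_comparison(pair) == Tristate.NOT_APPLICABLE


class TestPooledFixedEffect:
    def test_equal_ses_give_arithmetic_mean(self):
        pooled, _ = pooled_fixed_effect(
            SMDEstimate(smd=2.0, se=0.4), SMDEstimate(smd=1.0, se=0.4)
        )
        assert pooled.smd == pytest.approx(1.5)

    def test_hand_evaluated_weights(self):
        pooled, _ = pooled_fixed_effect(
            SMDEstimate(smd=2.0, se=0.5), SMDEstimate(smd=0.5, se=0.25)
        )
        assert pooled.smd == pytest.approx(0.8)
        assert pooled.se == pytest.approx(1.0 / math.sqrt(20.0))

    @given(
        a=st.floats(-3, 3), b=st.floats(-3, 3),
        sa=st.floats(0.05, 2), sb=st.floats(0.05, 2),
    )
    @settings(derandomize=True, max_examples=100)
    def test_bracketing_se_dominance_and_symmetry(self, a, b, sa, sb):
        x, y = SMDEstimate(smd=a, se=sa), SMDEstimate(smd=b, se=sb)
        pooled, p = pooled_fixed_effect(x, y)
        swapped, p2 = pooled_fixed_effect(y, x)
        assert min(a, b) - 1e-12 <= pooled.smd <= max(a, b) + 1e-12
        assert pooled.se <= min(sa, sb) + 1e-12
        assert pooled.smd == pytest.approx(swapped.smd, abs=1e-12)
        assert p == pytest.approx(p2, abs=1e-12)


class TestCriteriaVector:
    def test_perfect_replication_passes_all_five(self):
        a = criteria_vector(make_pair(1.0, 0.1, 1.0, 0.1))
        assert a.n_criteria_evaluable == 5
        assert a.n_criteria_success == 5
        assert a.same_direction == Tristate.SUCCESS

    def test_worked_failure_example(self):
        """Large shrunken original: four failures, pooled success, tally 1/5."""
        a = criteria_vector(make_pair(2.96, 0.6, 0.10, 0.25))
        assert a.significance_agreement == Tristate.FAILURE
        assert a.orig_in_rep_ci == Tristate.FAILURE
        assert a.rep_in_orig_ci == Tristate.FAILURE
        assert a.pi_success == Tristate.FAILURE
        assert a.p_orig == pytest.approx(1.1e-5, abs=3e-6)
        # hand-evaluated: w_o = 1/0.36, w_r = 16, est = (8.2222+1.6)/18.7778
        assert a.pooled is not None and a.pooled.smd == pytest.approx(0.5231, abs=1e-4)
        assert a.pooled_p == pytest.approx(0.0234, abs=5e-4)
        assert a.meta_significant == Tristate.SUCCESS
        assert (a.n_criteria_success, a.n_criteria_evaluable) == (1, 5)

    def test_image_only_pair_degrades_to_direction_only(self):
        pair = PairRecord(
            paper_id="p", experiment_id="e", effect_id="f", outcome_id="o",
            original=EffectEstimate(
                scale=EffectScale.IMAGE_ONLY, direction_label=DirectionLabel.POSITIVE
            ),
            replication=EffectEstimate(
                scale=EffectScale.IMAGE_ONLY, direction_label=DirectionLabel.POSITIVE
            ),
            reporting=Reporting.IMAGE,
        )
        a = criteria_vector(pair)
        assert a.n_criteria_evaluable == 0
        assert a.same_direction == Tristate.SUCCESS

    def test_null_original_meta_success_means_stayed_null(self):
        a = criteria_vector(
            make_pair(0.1, 0.5, 0.05, 0.4, interpretation=Interpretation.NULL)
        )
        assert a.meta_significant == Tristate.SUCCESS
        b = criteria_vector(
            make_pair(0.1, 0.2, 1.5, 0.2, interpretation=Interpretation.NULL)
        )
        assert b.meta_significant == Tristate.FAILURE

    def test_pooled_significant_in_wrong_direction_is_failure(self):
        a = criteria_vector(make_pair(0.3, 0.8, -2.0, 0.2))
        assert a.meta_significant == Tristate.FAILURE

    def test_noise_only_direction_rate_near_half(self, rng):
        """True effect 0 on both sides: same-direction succeeds ~50%,
        significance agreement ~alpha/2 (one direction)."""
        n = 10000
        est_o = rng.normal(0, 0.5, n)
        est_r = rng.normal(0, 0.5, n)
        successes = sig = 0
        for eo, er in zip(est_o, est_r):
            pair = make_pair(float(eo), 0.5, float(er), 0.5)
            if same_direction(pair) == Tristate.SUCCESS:
                successes += 1
            if significance_agreement(pair) == Tristate.SUCCESS:
                sig += 1
        assert successes / n == pytest.approx(0.5, abs=0.015)
        assert sig / n == pytest.approx(0.025, abs=0.01)

    def test_invalid_tau_rejected(self):
        with pytest.raises(InvalidInputError):
            HeterogeneityConfig(tau=-0.1)
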