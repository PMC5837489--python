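"""Cochran's Q tests, the significance gate, and analytic power."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mrscore import (
    GeneratingModel,
    PowerSpec,
    ScaledEstimate,
    ValidationError,
    binary_trait_power,
    cohort_to_sumstats,
    q_across,
    q_between,
    significance_gate,
    simulate_cohort,
)


class TestQBetween:
    def test_pooled_score_contrast_rounds_to_printed_p(self):
        # pooled CHD and IS genetic-score estimates on the log-odds scale
        res = q_between((-0.5089, 0.1058), (0.0694, 0.2021))
        assert res.q_stat == pytest.approx(6.43, abs=0.01)
        assert round(res.p_value, 2) == 0.01

    def test_identical_estimates_give_null_q(self):
        res = q_between((0.3, 0.1), (0.3, 0.2))
        assert res.q_stat == 0.0
        assert res.p_value == 1.0

    def test_symmetric_in_arguments(self):
        a, b = (-0.2, 0.15), (0.4, 0.3)
        assert q_between(a, b) == q_between(b, a)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValidationError):
            q_between((0.1, 0.0), (0.2, 0.1))


class TestQAcross:
    def test_equal_estimates_give_null_q(self):
        ests = [ScaledEstimate(f"rs{i}", "T", -0.4, 0.2 + 0.1 * i) for i in range(4)]
        res = q_across(ests)
        assert res.q_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(-2, 2, allow_nan=False),
        st.floats(-2, 2, allow_nan=False),
        st.floats(0.05, 2, allow_nan=False),
        st.floats(0.05, 2, allow_nan=False),
    )
    def test_k2_equals_q_between(self, b1, b2, s1, s2):
        ests = [ScaledEstimate("rs1", "T", b1, s1), ScaledEstimate("rs2", "T", b2, s2)]
        across = q_across(ests)
        between = q_between((b1, s1), (b2, s2))
        assert across.q_stat == pytest.approx(between.q_stat, rel=1e-10, abs=1e-12)
        assert across.df == between.df == 1

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValidationError):
            q_across([ScaledEstimate("rs1", "T", 0.0, 1.0)])

    def test_six_variant_chd_heterogeneity_direction(self, table1):
        """Scaled CHD effects are heterogeneous (p < 0.05); IS effects are not."""
        from mrscore import wald_ratio

        results = {}
        for trait in ("CHD", "IS"):
            scaled = [
                wald_ratio(
                    table1.get(v, trait).beta,
                    table1.get(v, trait).se,
                    table1.get(v, "LDL-C").beta,
                    variant_id=v,
                    trait=trait,
                )
                for v in table1.variant_ids()
            ]
            results[trait] = q_across(scaled)
        assert results["CHD"].p_value < 0.05
        assert results["IS"].p_value > 0.05


class TestPower:
    def test_stroke_sample_has_about_85_percent_power_for_chd_size_effect(self):
        spec = PowerSpec(
            eaf=0.015, n_case=10307, n_control=19326,
            alt_log_or=math.log(0.77), alpha=0.008,
        )
        power = binary_trait_power(spec)
        assert power >= 0.80
        assert power == pytest.approx(0.8489, abs=0.005)

    def test_null_alternative_returns_half_alpha(self):
        spec = PowerSpec(eaf=0.2, n_case=500, n_control=500, alt_log_or=0.0, alpha=0.05)
        assert binary_trait_power(spec) == pytest.approx(0.025, rel=1e-6)

    def test_monotone_in_sample_size_and_effect(self):
        base = PowerSpec(eaf=0.2, n_case=500, n_control=800, alt_log_or=0.2, alpha=0.05)
        bigger_n = PowerSpec(eaf=0.2, n_case=1000, n_control=1600, alt_log_or=0.2, alpha=0.05)
        bigger_b = PowerSpec(eaf=0.2, n_case=500, n_control=800, alt_log_or=0.3, alpha=0.05)
        assert binary_trait_power(bigger_n) > binary_trait_power(base)
        assert binary_trait_power(bigger_b) > binary_trait_power(base)

    def test_invariant_under_case_control_swap_and_sign(self):
        a = PowerSpec(eaf=0.1, n_case=400, n_control=900, alt_log_or=0.25, alpha=0.01)
        b = PowerSpec(eaf=0.1, n_case=900, n_control=400, alt_log_or=-0.25, alpha=0.01)
        assert binary_trait_power(a) == pytest.approx(binary_trait_power(b), rel=1e-12)

    def test_observed_se_variant(self):
        spec = PowerSpec(eaf=0.1, n_case=400, n_control=900, alt_log_or=0.25, alpha=0.01)
        assert binary_trait_power(spec, se=0.05) > binary_trait_power(spec, se=0.2)

    def test_degenerate_eaf_rejected(self):
        with pytest.raises(ValidationError):
            PowerSpec(eaf=0.0, n_case=10, n_control=10, alt_log_or=0.1, alpha=0.05)

    def test_empirical_power_matches_analytic_within_five_points(self):
        """Monte-Carlo rejection rate of the per-allele Wald test at the
        alternative tracks the closed-form power (1000 replicates)."""
        n, freq, theta, eff, base = 4000, 0.3, -0.3, -0.5, -0.7
        geno_p = np.array([(1 - freq) ** 2, 2 * freq * (1 - freq), freq ** 2])
        logits = base + theta * (-eff) * np.arange(3)
        p_case = float(geno_p @ (1 / (1 + np.exp(-logits))))
        n_case = round(n * p_case)
        spec = PowerSpec(
            eaf=freq, n_case=n_case, n_control=n - n_case,
            alt_log_or=abs(theta * eff), alpha=0.05,
        )
        analytic = binary_trait_power(spec)
        rejections = 0
        for s in range(1000):
            model = GeneratingModel(
                n_individuals=n,
                variants=(("v1", freq),),
                per_allele_ldl_effects=(eff,),
                theta_by_trait={"T": theta},
                baseline_log_odds={"T": base},
                seed=50_000 + s,
            )
            panel = cohort_to_sumstats(simulate_cohort(model))[0]
            record = panel.get("v1", "T")
            p = 2 * stats.norm.sf(abs(record.beta) / record.se)
            rejections += p < 0.05
        assert rejections / 1000 == pytest.approx(analytic, abs=0.05)


class TestSignificanceGate:
    @pytest.mark.parametrize(
        "p, alpha, expected",
        [(7e-6, 0.008, True), (0.74, 0.008, False), (0.008, 0.008, False)],
    )
    def test_strict_threshold(self, p, alpha, expected):
        assert significance_gate(p, alpha) is expected

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            significance_gate(0.0, 0.05)
        with pytest.raises(ValidationError):
            significance_gate(0.5, 1.5)
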