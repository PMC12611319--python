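import numpy as np
import pytest

from medimr.estimators import MRResults
from medimr.mediation import (MediationModel, assemble_pathway,
                              bidirectional_screen, mediated_effect,
                              mediated_proportion, path_from_odds_ratios)


def res(beta, se, pvalue=None):
    return MRResults(method="ivw_mre", beta=beta, se=se, n_snps=10,
                     pvalue=pvalue)


class TestBidirectionalScreen:
    def test_forward_significant_reverse_null_passes(self):
        s = bidirectional_screen(res(0.2, 0.08, pvalue=0.016),
                                 res(0.01, 0.05, pvalue=0.40))
        assert s.passed

    def test_no_forward_effect_fails(self):
        s = bidirectional_screen(res(0.05, 0.05, pvalue=0.2),
                                 res(0.01, 0.05, pvalue=0.40))
        assert not s.passed
        assert "no forward effect" in s.reasons

    def test_reverse_causation_fails(self):
        s = bidirectional_screen(res(0.2, 0.05, pvalue=0.01),
                                 res(0.2, 0.05, pvalue=0.01))
        assert not s.passed
        assert "reverse causation" in s.reasons

    def test_missing_reverse_leg_counts_as_null(self):
        s = bidirectional_screen(res(0.2, 0.05, pvalue=0.01), None)
        assert s.passed
        assert any("not estimable" in r for r in s.reasons)


class TestMediatedEffect:
    def test_published_arithmetic_from_leg_odds_ratios(self):
        a = res(np.log(0.912), 0.0396)
        b = res(np.log(1.244), 0.0792)
        ab, se, ci, p = mediated_effect(a, b)
        assert round(ab, 3) == -0.020

    def test_zero_a_path(self):
        a = res(0.0, 0.05)
        b = res(0.3, 0.02)
        ab, se, ci, p = mediated_effect(a, b)
        assert ab == 0.0
        assert se == pytest.approx(0.3 * 0.05)

    def test_sobel_se_matches_monte_carlo_product(self, rng):
        a_beta, se_a = -0.0921, 0.0396
        b_beta, se_b = 0.2183, 0.0792
        ab, se, *_ = mediated_effect(res(a_beta, se_a), res(b_beta, se_b))
        assert se == pytest.approx(0.0113, abs=0.0002)
        draws = rng.normal(a_beta, se_a, 1_000_000) * \
            rng.normal(b_beta, se_b, 1_000_000)
        ab2, se2, *_ = mediated_effect(res(a_beta, se_a), res(b_beta, se_b),
                                       second_order=True)
        assert se2 == pytest.approx(np.std(draws), rel=0.02)

    def test_symmetric_in_a_and_b(self):
        a, b = res(-0.1, 0.03), res(0.25, 0.06)
        assert mediated_effect(a, b)[:2] == mediated_effect(b, a)[:2]

    def test_ci_symmetric_about_estimate(self):
        ab, se, (lo, hi), _ = mediated_effect(res(0.1, 0.02), res(0.3, 0.05))
        assert (hi - ab) == pytest.approx(ab - lo)


class TestMediatedProportion:
    def test_published_percentages(self):
        for or_a, or_b, or_c, printed in [
                (0.912, 1.244, 0.863, 13.60), (0.893, 1.244, 0.803, 11.20),
                (1.125, 0.915, 0.883, 8.37), (1.140, 1.244, 1.138, 22.10)]:
            _, prop = path_from_odds_ratios(or_a, or_b, or_c)
            assert 100 * prop == pytest.approx(printed, abs=0.15)

    def test_full_mediation_is_hundred_percent(self):
        prop, flag = mediated_proportion(0.2, 0.2)
        assert prop == 1.0 and not flag

    def test_zero_total_effect_is_hard_error(self):
        with pytest.raises(ZeroDivisionError):
            mediated_proportion(0.1, 0.0)

    def test_inconsistent_mediation_flagged(self):
        _, flag = mediated_proportion(-0.1, 0.2)
        assert flag
        _, flag = mediated_proportion(0.3, 0.2)
        assert flag  # proportion > 1


class TestAssemblePathway:
    def legs(self, p_b=None):
        a = res(0.21, 0.018)
        b = res(0.21, 0.024, pvalue=p_b)
        c = res(0.19, 0.019)
        rev = res(0.01, 0.05, pvalue=0.6)
        return a, b, c, rev

    def test_all_significant_path_included(self):
        a, b, c, rev = self.legs()
        path = assemble_pathway(a, b, c, reverse=rev)
        assert path.included
        assert path.mediated == pytest.approx(a.beta * b.beta)

    def test_identity_c_prime_plus_ab_equals_c(self):
        a, b, c, rev = self.legs()
        path = assemble_pathway(a, b, c, reverse=rev)
        assert path.c_prime + path.mediated == pytest.approx(path.c, abs=0)

    def test_nonsignificant_mediator_leg_excluded(self):
        a, b, c, rev = self.legs(p_b=0.3)
        path = assemble_pathway(a, b, c, reverse=rev)
        assert not path.included
        assert "mediator->outcome not significant" in path.exclusion_reasons

    def test_qc_failure_excludes_with_reason(self):
        a, b, c, rev = self.legs()
        path = assemble_pathway(a, b, c, reverse=rev, qc_pass=False,
                                qc_reasons=["heterogeneity"])
        assert not path.included
        assert "qc:heterogeneity" in path.exclusion_reasons

    def test_missing_leg_is_hard_error(self):
        a, b, c, _ = self.legs()
        with pytest.raises(ValueError, match="missing leg"):
            MediationModel(a, None, c)

    def test_summary_prints_proportion(self):
        a, b, c, rev = self.legs()
        path = assemble_pathway(a, b, c, reverse=rev)
        assert "%" in path.summary()


def test_delta_ci_covers_under_strong_signal(rng):
    # coverage of the first-order CI when both legs have |effect|/se > 4
    a_true, b_true, se_a, se_b = 0.2, 0.25, 0.02, 0.03
    n = 1000
    hits = 0
    for _ in range(n):
        a_hat = rng.normal(a_true, se_a)
        b_hat = rng.normal(b_true, se_b)
        _, _, (lo, hi), _ = mediated_effect(res(a_hat, se_a), res(b_hat, se_b))
        hits += lo <= a_true * b_true <= hi
    assert 0.92 <= hits / n <= 0.98
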