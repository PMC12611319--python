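import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from medimr.estimators import MRModel, egger, ivw, wald_ratio, weighted_median
from medimr.records import HarmonizedPair

from conftest import make_pairs


class TestWaldRatio:
    def test_direct_ratio(self):
        p = make_pairs([1.0], [0.1], [0.5], [0.1])[0]
        res = wald_ratio(p)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1)

    def test_zero_outcome_effect(self):
        p = make_pairs([2.0], [0.1], [0.0], [0.1])[0]
        assert wald_ratio(p).beta == 0.0

    def test_zero_exposure_effect_is_hard_error(self):
        p = make_pairs([0.0], [0.1], [0.5], [0.1])[0]
        with pytest.raises(ZeroDivisionError, match="undefined ratio"):
            wald_ratio(p)

    def test_second_order_se_matches_monte_carlo(self, rng):
        bx, sx, by, sy = 0.5, 0.02, 0.3, 0.04
        p = make_pairs([bx], [sx], [by], [sy])[0]
        res = wald_ratio(p, second_order=True)
        num = rng.normal(by, sy, 1_000_000)
        den = rng.normal(bx, sx, 1_000_000)
        mc_sd = np.std(num / den)
        assert res.se == pytest.approx(mc_sd, rel=0.02)


class TestIVW:
    def test_consensus_ratios_give_exact_estimate(self):
        pairs = make_pairs([1.0, 2.0], [0.1, 0.1], [0.2, 0.4], [0.1, 0.1])
        fe = ivw(pairs, model="fixed")
        mre = ivw(pairs, model="mre")
        assert fe.beta == pytest.approx(0.2)
        assert mre.beta == pytest.approx(0.2)
        assert mre.se == pytest.approx(fe.se)  # Q = 0

    def test_closed_form_weighted_least_squares(self):
        pairs = make_pairs([1.0, 1.0], [0.1, 0.1], [0.3, 0.1], [0.1, 0.1])
        res = ivw(pairs, model="fixed")
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(np.sqrt(1 / 200))

    def test_or_and_ci_exponentiation(self):
        from medimr.estimators import MRResults
        res = MRResults(method="ivw_mre", beta=0.21833, se=0.07926, n_snps=10)
        lo, hi = res.or_ci
        assert round(res.odds_ratio, 3) == 1.244
        assert round(lo, 3) == 1.065
        assert round(hi, 3) == 1.453

    def test_single_pair_delegates_to_wald(self):
        pairs = make_pairs([0.5], [0.1], [0.25], [0.1])
        res = ivw(pairs)
        assert res.beta == pytest.approx(0.5)
        assert res.se == pytest.approx(0.1 / 0.5)

    def test_all_zero_exposure_is_hard_error(self):
        pairs = make_pairs([0.0, 0.0], [0.1, 0.1], [0.1, 0.2], [0.1, 0.1])
        with pytest.raises(ZeroDivisionError):
            ivw(pairs)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_joint_sign_flip_invariance(self, seed):
        rng = np.random.default_rng(seed)
        J = 8
        bx = rng.normal(0.2, 0.05, J)
        by = rng.normal(0.05, 0.02, J)
        sy = rng.uniform(0.01, 0.05, J)
        sx = np.full(J, 0.02)
        base = ivw(make_pairs(bx, sx, by, sy)).beta
        flip = rng.random(J) < 0.5
        sgn = np.where(flip, -1.0, 1.0)
        flipped = ivw(make_pairs(bx * sgn, sx, by * sgn, sy)).beta
        assert flipped == pytest.approx(base, rel=1e-12)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_mre_se_never_below_fixed_effect_se(self, seed):
        rng = np.random.default_rng(seed)
        J = 10
        pairs = make_pairs(rng.normal(0.2, 0.05, J), np.full(J, 0.02),
                           rng.normal(0.05, 0.05, J),
                           rng.uniform(0.01, 0.05, J))
        fe, mre = ivw(pairs, "fixed"), ivw(pairs, "mre")
        assert mre.beta == pytest.approx(fe.beta, rel=1e-12)
        assert mre.se >= fe.se - 1e-15


class TestEgger:
    def test_exact_line_recovered(self):
        pairs = make_pairs([1.0, 2.0, 3.0], [0.1] * 3, [0.3, 0.5, 0.7],
                           [0.1] * 3)
        res = egger(pairs)
        assert res.egger_intercept == pytest.approx(0.1, abs=1e-10)
        assert res.beta == pytest.approx(0.2, abs=1e-10)

    def test_fewer_than_three_pairs_rejected(self):
        pairs = make_pairs([1.0, 2.0], [0.1] * 2, [0.3, 0.5], [0.1] * 2)
        with pytest.raises(ValueError, match="underdetermined"):
            egger(pairs)

    def test_orientation_makes_fit_sign_invariant(self, rng):
        J = 20
        bx = rng.normal(0.2, 0.05, J)
        by = 0.3 * bx + rng.normal(0, 0.02, J)
        pairs = make_pairs(bx, np.full(J, 0.02), by, np.full(J, 0.02))
        base = egger(pairs)
        sgn = np.where(rng.random(J) < 0.5, -1.0, 1.0)
        flipped = egger(make_pairs(bx * sgn, np.full(J, 0.02), by * sgn,
                                   np.full(J, 0.02)))
        assert flipped.beta == pytest.approx(base.beta, rel=1e-10)
        assert flipped.egger_intercept == pytest.approx(base.egger_intercept,
                                                        rel=1e-10)


class TestWeightedMedian:
    def test_hand_traced_cumulative_weights(self):
        # ratios {0.1, 0.2, 0.3} with equal weights: s = {1/6, 1/2, 5/6},
        # s = 0.5 lands exactly on the middle ratio
        pairs = make_pairs([1.0, 1.0, 1.0], [0.1] * 3, [0.1, 0.2, 0.3],
                           [0.1] * 3)
        res = weighted_median(pairs, n_boot=100, seed=1)
        assert res.beta == pytest.approx(0.2)

    def test_identical_ratios_and_small_bootstrap_se(self):
        pairs = make_pairs([1.0, 2.0, 4.0], [0.001] * 3, [0.3, 0.6, 1.2],
                           [0.001] * 3)
        res = weighted_median(pairs, n_boot=200, seed=1)
        assert res.beta == pytest.approx(0.3)
        assert res.se < 0.01

    def test_equal_weights_odd_j_is_sample_median(self, rng):
        J = 7
        by = rng.normal(0.2, 0.1, J)
        pairs = make_pairs(np.ones(J), np.full(J, 0.01), by, np.full(J, 0.05))
        res = weighted_median(pairs, n_boot=50, seed=2)
        assert res.beta == pytest.approx(np.median(by), rel=1e-9)

    def test_seeded_bootstrap_reproducible(self):
        pairs = make_pairs([1.0, 1.0, 1.0, 1.0], [0.05] * 4,
                           [0.1, 0.2, 0.25, 0.3], [0.05] * 4)
        a = weighted_median(pairs, n_boot=200, seed=9)
        b = weighted_median(pairs, n_boot=200, seed=9)
        assert a.se == b.se


def test_all_estimators_exact_on_noise_free_data(rng):
    J = 15
    bx = rng.uniform(0.1, 0.3, J)
    by = 0.25 * bx
    pairs = make_pairs(bx, np.full(J, 0.02), by, np.full(J, 0.02))
    assert ivw(pairs).beta == pytest.approx(0.25, abs=1e-12)
    e = egger(pairs)
    assert e.beta == pytest.approx(0.25, abs=1e-10)
    assert e.egger_intercept == pytest.approx(0.0, abs=1e-10)
    assert weighted_median(pairs, n_boot=50, seed=3).beta == \
        pytest.approx(0.25, abs=1e-12)


def test_model_results_summary_mentions_method(small_stats):
    pairs = make_pairs([1.0, 1.0], [0.1, 0.1], [0.3, 0.1], [0.1, 0.1])
    model = MRModel(pairs, exposure="lipid", outcome="longevity")
    res = model.fit("ivw", model="fixed")
    text = res.summary()
    assert "ivw_fe" in text and "lipid" in text
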