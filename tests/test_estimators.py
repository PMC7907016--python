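"""Causal estimator suite: Wald ratios, IVW, ML, median, mode, Egger."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_instruments, random_instruments
from mrkit.estimators import (
    InsufficientInstrumentsError,
    cochran_q,
    egger,
    ivw,
    maximum_likelihood,
    median_estimator,
    mode_estimator,
    penalized_robust_ivw,
    wald_ratio,
)

# Frozen oracle values, computed by hand meta-analysis of the nine
# bundled instruments with weights beta_x^2 / se_y^2.
FIXTURE_IVW_BETA = 0.13076037397828166
FIXTURE_IVW_SE = 0.16561279319259373
FIXTURE_Q = 7.201980958550777


class TestWaldRatio:
    def test_fixture_snp_first_order(self, fixture9):
        inst = next(i for i in fixture9 if i.snp_id == "rs234709")
        ratio, se = wald_ratio(inst)
        assert ratio == pytest.approx(0.6466866, rel=1e-6)  # 0.0464321/0.0718
        assert se == pytest.approx(0.3721811, rel=1e-6)  # 0.0267226/0.0718

    def test_zero_numerator(self):
        inst = make_instruments([0.1], [0.01], [0.0], [0.02])[0]
        ratio, se = wald_ratio(inst)
        assert ratio == 0.0
        assert se == pytest.approx(0.2)

    def test_antisymmetry_in_outcome(self, fixture9):
        inst = fixture9[0]
        flipped = dataclasses.replace(inst, beta_out=-inst.beta_out)
        r1, s1 = wald_ratio(inst)
        r2, s2 = wald_ratio(flipped)
        assert r2 == -r1 and s2 == s1

    def test_second_order_exceeds_first(self, fixture9):
        inst = fixture9[0]
        _, first = wald_ratio(inst, "first")
        _, second = wald_ratio(inst, "second")
        assert second > first

    def test_zero_exposure_beta_raises(self):
        inst = make_instruments([0.0], [0.01], [0.1], [0.02])[0]
        with pytest.raises(ZeroDivisionError):
            wald_ratio(inst)


class TestIvw:
    def test_fixture_point_estimate_and_se(self, fixture9):
        est = ivw(fixture9)
        assert est.beta == pytest.approx(FIXTURE_IVW_BETA, rel=1e-12)
        assert est.se == pytest.approx(FIXTURE_IVW_SE, rel=1e-12)

    def test_fixture_reproduces_published_row(self, fixture9):
        est = ivw(fixture9)
        assert f"{est.or_:.2f}" == "1.14"
        assert f"{est.or_ci_low:.2f}" == "0.82"
        assert f"{est.or_ci_high:.2f}" == "1.58"
        assert f"{est.pval:.2f}" == "0.43"

    def test_identical_ratios_degenerate(self):
        inst = make_instruments([0.1, 0.2], [0.01, 0.01], [0.05, 0.1], [0.02, 0.03])
        fixed = ivw(inst, "fixed")
        rand = ivw(inst, "random")
        assert fixed.beta == pytest.approx(0.5, rel=1e-12)
        assert cochran_q(inst).q == pytest.approx(0.0, abs=1e-20)
        assert rand.se == fixed.se

    def test_requires_two_instruments(self, fixture9):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(fixture9[:1])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_ratio_meta_equals_zero_intercept_wls(self, seed):
        """IVW two ways: ratio meta-analysis vs weighted regression."""
        rng = np.random.default_rng(seed)
        inst = random_instruments(rng, int(rng.integers(2, 30)))
        est = ivw(inst)
        bx = np.array([i.beta_exp for i in inst])
        by = np.array([i.beta_out for i in inst])
        w = np.array([1 / i.se_out**2 for i in inst])
        slope = np.sum(w * bx * by) / np.sum(w * bx * bx)
        assert est.beta == pytest.approx(slope, rel=1e-11)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_effects_se_never_below_fixed(self, seed):
        rng = np.random.default_rng(seed)
        inst = random_instruments(rng, int(rng.integers(2, 20)))
        fixed, rand = ivw(inst, "fixed"), ivw(inst, "random")
        assert rand.se >= fixed.se
        q = cochran_q(inst)
        if q.q <= q.df:
            assert rand.se == fixed.se
        else:
            assert rand.se > fixed.se


class TestCochranQ:
    def test_fixture_value_below_df(self, fixture9):
        het = cochran_q(fixture9)
        assert het.q == pytest.approx(FIXTURE_Q, rel=1e-12)
        assert het.df == 8
        assert het.q < het.df  # hence random-effects IVW == fixed
        assert het.i2 == 0.0

    def test_permutation_invariance(self, fixture9):
        shuffled = list(fixture9)[::-1]
        assert cochran_q(shuffled).q == pytest.approx(cochran_q(fixture9).q, rel=1e-12)


class TestMaximumLikelihood:
    def test_fixture_reproduces_published_row(self, fixture9):
        est = maximum_likelihood(fixture9)
        assert f"{est.or_:.2f}" == "1.14"
        assert f"{est.or_ci_low:.2f}" == "0.82"
        assert f"{est.or_ci_high:.2f}" == "1.58"
        assert f"{est.pval:.2f}" == "0.43"

    def test_small_exposure_noise_limit_is_ivw(self, fixture9):
        shrunk = [dataclasses.replace(i, se_exp=i.se_exp * 1e-6) for i in fixture9]
        est = maximum_likelihood(shrunk)
        assert est.beta == pytest.approx(FIXTURE_IVW_BETA, rel=1e-5)
        assert est.se == pytest.approx(FIXTURE_IVW_SE, rel=1e-4)


class TestMedian:
    def test_fixture_simple_median_is_middle_sorted_ratio(self, fixture9):
        # Equal weights with odd J put cumulative midpoint 0.5 exactly on
        # the 5th sorted ratio.
        est = median_estimator(fixture9, "simple", n_boot=50, seed=1)
        ratios = sorted(i.beta_out / i.beta_exp for i in fixture9)
        assert est.beta == pytest.approx(ratios[4], rel=1e-12)
        assert f"{est.or_:.2f}" == "1.15"

    def test_fixture_weighted_median(self, fixture9):
        est = median_estimator(fixture9, "weighted", n_boot=50, seed=1)
        assert f"{est.or_:.2f}" == "1.16"

    def test_identical_ratios_return_common_value(self):
        inst = make_instruments(
            [0.1, 0.2, 0.4], [0.01] * 3, [0.03, 0.06, 0.12], [0.02] * 3
        )
        for weighting in ("simple", "weighted"):
            est = median_estimator(inst, weighting, n_boot=20, seed=0)
            assert est.beta == pytest.approx(0.3, rel=1e-12)

    def test_bootstrap_reproducible_under_seed(self, fixture9):
        a = median_estimator(fixture9, "weighted", n_boot=100, seed=7)
        b = median_estimator(fixture9, "weighted", n_boot=100, seed=7)
        assert a.se == b.se

    def test_permutation_invariance(self, fixture9):
        a = median_estimator(fixture9, "simple", n_boot=10, seed=3)
        b = median_estimator(list(fixture9)[::-1], "simple", n_boot=10, seed=3)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)

    def test_requires_three_instruments(self, fixture9):
        with pytest.raises(InsufficientInstrumentsError):
            median_estimator(fixture9[:2], "simple", n_boot=10, seed=0)


class TestMode:
    def test_fixture_reproduces_published_rows(self, fixture9):
        simple = mode_estimator(fixture9, "simple", n_boot=50, seed=1)
        weighted = mode_estimator(fixture9, "weighted", n_boot=50, seed=1)
        assert f"{simple.or_:.2f}" == "1.28"
        assert f"{weighted.or_:.2f}" == "1.46"

    def test_majority_cluster_wins(self):
        # Three tight ratios at 0.3 and one gross outlier at 3.0.
        inst = make_instruments(
            [0.1, 0.12, 0.15, 0.1],
            [0.005] * 4,
            [0.03, 0.036, 0.045, 0.30],
            [0.004] * 4,
        )
        est = mode_estimator(inst, "simple", n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.05)

    def test_identical_ratios_degenerate(self):
        inst = make_instruments([0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.1, 0.2], [0.02] * 3)
        est = mode_estimator(inst, "simple", n_boot=20, seed=0)
        assert est.beta == pytest.approx(0.5, rel=1e-12)
        assert est.se == 0.0
        assert "degenerate" in est.method

    def test_permutation_invariance(self, fixture9):
        a = mode_estimator(fixture9, "weighted", n_boot=10, seed=3)
        b = mode_estimator(list(fixture9)[::-1], "weighted", n_boot=10, seed=3)
        assert a.beta == pytest.approx(b.beta, rel=1e-9)


class TestEgger:
    def test_fixture_reproduces_published_slope_and_intercept(self, fixture9):
        res = egger(fixture9)
        assert f"{res.slope.or_:.2f}" == "1.70"
        assert f"{res.slope.or_ci_low:.2f}" == "0.69"
        assert f"{res.slope.or_ci_high:.2f}" == "4.24"
        assert f"{res.slope.pval:.2f}" == "0.25"
        assert f"{res.intercept:.2f}" == "-0.03"
        assert f"{res.intercept_ci_low:.2f}" == "-0.08"
        assert f"{res.intercept_ci_high:.2f}" == "0.03"
        assert f"{res.intercept_pval:.2f}" == "0.35"

    def test_exact_line_recovered(self):
        # Collinear points on y = 2x - 1: slope and intercept exact.
        inst = make_instruments([1, 2, 3], [0.1] * 3, [1, 3, 5], [0.5, 0.2, 0.9])
        res = egger(inst)
        assert res.slope.beta == pytest.approx(2.0, rel=1e-12)
        assert res.intercept == pytest.approx(-1.0, rel=1e-12)

    def test_outcome_shift_moves_only_intercept(self, fixture9):
        res = egger(fixture9)
        shifted = [
            dataclasses.replace(i, beta_out=i.beta_out + 0.05) for i in fixture9
        ]
        res2 = egger(shifted)
        assert res2.slope.beta == pytest.approx(res.slope.beta, rel=1e-9)
        assert res2.intercept == pytest.approx(res.intercept + 0.05, rel=1e-9)

    def test_sign_flip_of_one_instrument_is_invariant(self, fixture9):
        flipped = [
            dataclasses.replace(i, beta_exp=-i.beta_exp, beta_out=-i.beta_out)
            if j == 3
            else i
            for j, i in enumerate(fixture9)
        ]
        res, res2 = egger(fixture9), egger(flipped)
        assert res2.slope.beta == pytest.approx(res.slope.beta, rel=1e-12)
        assert res2.intercept == pytest.approx(res.intercept, rel=1e-12)
        assert res2.slope.se == pytest.approx(res.slope.se, rel=1e-12)

    def test_intercept_ci_brackets_estimate(self, fixture9):
        res = egger(fixture9)
        assert res.intercept_ci_low <= res.intercept <= res.intercept_ci_high


class TestPenalizedRobustIvw:
    def test_fixture_reproduces_published_point_estimate(self, fixture9):
        est = penalized_robust_ivw(fixture9)
        assert f"{est.or_:.2f}" == "1.14"

    def test_no_heterogeneity_means_no_penalty(self):
        # Ratios nearly identical: all per-SNP Q contributions tiny, so the
        # penalized robust fit matches plain IVW closely.
        rng = np.random.default_rng(5)
        bx = rng.uniform(0.05, 0.2, 10)
        by = 0.4 * bx + rng.normal(0, 1e-5, 10)
        inst = make_instruments(bx, [0.01] * 10, by, [0.03] * 10)
        est = penalized_robust_ivw(inst)
        assert est.beta == pytest.approx(ivw(inst).beta, rel=1e-3)

    def test_outlier_resistance(self):
        # 20 tight instruments on theta=0.3 plus one SNP with a 10-SE
        # displaced outcome beta: the robust estimate stays with the
        # outlier-free IVW while plain IVW is pulled away.
        rng = np.random.default_rng(11)
        theta = 0.3
        bx = rng.uniform(0.08, 0.2, 21)
        sy = np.full(21, 0.004)
        by = theta * bx + rng.normal(0, sy)
        by[0] += 10 * sy[0]
        inst = make_instruments(bx, [0.005] * 21, by, sy)
        clean = ivw(make_instruments(bx[1:], [0.005] * 20, by[1:], sy[1:]))
        robust = penalized_robust_ivw(inst)
        plain = ivw(inst)
        assert abs(robust.beta - clean.beta) < 0.5 * clean.se
        assert abs(plain.beta - theta) > abs(robust.beta - theta)
        assert abs(robust.beta - theta) < 2 * robust.se
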