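"""Unit and property tests for the MR estimators."""

import numpy as np
import pytest

from pqtlmr import (
    InsufficientInstrumentsError,
    cochran_q,
    cochran_q_pvalue,
    ivw,
    mr_auto,
    mr_egger,
    wald_ratio,
    weighted_median,
    weighted_mode,
)

from conftest import make_harmonized


class TestWaldRatio:
    def test_null_outcome_gives_zero_effect_p_one(self):
        est = wald_ratio(0.2, 0.01, 0.0, 0.05)
        assert est.beta == 0.0
        assert est.pval == 1.0

    def test_hand_arithmetic(self):
        est = wald_ratio(0.2, 0.01, 0.06, 0.05)
        assert est.beta == pytest.approx(0.3)
        assert est.se == pytest.approx(0.25)
        assert est.ci_low == pytest.approx(0.3 - 1.96 * 0.25)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.06, 0.05)


class TestIVW:
    def test_hand_arithmetic(self):
        data = make_harmonized([0.1, 0.2], [0.05, 0.10], byse=[0.1, 0.1])
        est = ivw(data, mode="fixed")
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(1 / np.sqrt((0.01 + 0.04) / 0.01))

    def test_proportional_data_exact_and_modes_agree(self, proportional_data):
        fixed = ivw(proportional_data, mode="fixed")
        random = ivw(proportional_data, mode="multiplicative_random")
        assert fixed.beta == pytest.approx(0.5, abs=1e-14)
        assert random.se == pytest.approx(fixed.se)  # residual scale floored at 1

    def test_equals_weighted_mean_of_ratios(self):
        # algebraic identity: IVW beta = sum(w_j ratio_j)/sum(w_j), w=(bx/byse)^2
        rng = np.random.default_rng(7)
        for _ in range(20):
            bx = rng.uniform(0.05, 0.4, 8) * rng.choice([-1, 1], 8)
            by = rng.normal(0, 0.1, 8)
            byse = rng.uniform(0.01, 0.2, 8)
            data = make_harmonized(bx, by, byse=byse)
            w = (bx / byse) ** 2
            expected = np.sum(w * (by / bx)) / np.sum(w)
            assert ivw(data, "fixed").beta == pytest.approx(expected, rel=1e-12)

    def test_single_instrument_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            ivw(make_harmonized([0.1], [0.05]))


class TestEgger:
    def test_exact_linear_data(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        est = mr_egger(make_harmonized(bx, 0.1 + 0.5 * bx, byse=np.full(4, 0.05)))
        assert est.beta == pytest.approx(0.5, abs=1e-10)
        assert est.extra["intercept"] == pytest.approx(0.1, abs=1e-10)

    def test_orientation_invariance(self):
        # flipping the coded allele of an instrument must not change the fit
        bx = np.array([0.1, -0.2, 0.3, 0.4])
        by = 0.1 * np.sign(bx) + 0.5 * bx
        est = mr_egger(make_harmonized(bx, by, byse=np.full(4, 0.05)))
        est_flip = mr_egger(make_harmonized(-bx, -by, byse=np.full(4, 0.05)))
        assert est.beta == pytest.approx(est_flip.beta)
        assert est.extra["intercept"] == pytest.approx(est_flip.extra["intercept"])

    def test_two_instruments_raise(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_harmonized([0.1, 0.2], [0.05, 0.1]))


class TestWeightedMedian:
    def test_constant_ratios(self, proportional_data):
        est = weighted_median(proportional_data, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_symmetric_ratios_equal_weights(self):
        bx = np.full(3, 0.2)
        by = 0.2 * np.array([0.1, 0.5, 0.9])
        est = weighted_median(make_harmonized(bx, by, byse=np.full(3, 0.05)),
                              n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_robust_to_minority_pleiotropy(self):
        # 60% of weight valid at ratio 0.3, 40% wildly pleiotropic at 2.0
        rng = np.random.default_rng(11)
        med_err, ivw_err = [], []
        for _ in range(100):
            bx = np.full(10, 0.2)
            ratios = np.array([0.3] * 6 + [2.0] * 4)
            by = ratios * bx + rng.normal(0, 0.005, 10)
            data = make_harmonized(bx, by, byse=np.full(10, 0.005))
            med_err.append(weighted_median(data, n_boot=10, seed=0).beta - 0.3)
            ivw_err.append(ivw(data, "fixed").beta - 0.3)
        assert abs(np.mean(med_err)) < 0.05
        assert np.mean(ivw_err) > 0.5  # IVW absorbs the pleiotropic 40%


class TestWeightedMode:
    def test_constant_ratios(self, proportional_data):
        est = weighted_mode(proportional_data, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.5)

    def test_modal_cluster_wins(self):
        bx = np.full(4, 0.2)
        by = np.array([0.3, 0.3, 0.3, 0.9]) * bx
        est = weighted_mode(make_harmonized(bx, by, byse=np.full(4, 0.05)),
                            n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.3, abs=0.02)

    def test_huge_bandwidth_approaches_weighted_mean(self):
        bx = np.array([0.1, 0.2, 0.4])
        by = np.array([0.02, 0.08, 0.1])
        byse = np.array([0.05, 0.02, 0.04])
        data = make_harmonized(bx, by, byse=byse)
        w = (bx / byse) ** 2
        wmean = np.sum(w * by / bx) / np.sum(w)
        est = weighted_mode(data, bandwidth_factor=500.0, n_boot=10, seed=0)
        # argmax restricted to [min, max] of ratios; huge smoothing pulls it
        # onto the weighted mean when that lies inside the ratio range
        assert est.beta == pytest.approx(wmean, abs=0.02)


class TestCochranQ:
    @pytest.mark.parametrize("q,df,expected", [
        (0.671, 2, 7.15e-01),
        (6.666, 1, 9.83e-03),
        (0.309, 1, 5.78e-01),
    ])
    def test_reported_heterogeneity_pvalues(self, q, df, expected):
        assert cochran_q_pvalue(q, df) == pytest.approx(expected, rel=5e-3)

    def test_proportional_data_has_no_heterogeneity(self, proportional_data):
        res = cochran_q(proportional_data)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        assert res.pval == pytest.approx(1.0)
        assert res.df == proportional_data.nsnp - 1

    def test_single_instrument_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            cochran_q(make_harmonized([0.1], [0.05]))


class TestMrAuto:
    def test_single_instrument_dispatches_to_wald(self):
        data = make_harmonized([0.2], [0.06], byse=[0.05])
        res = mr_auto(data)
        assert set(res.estimates) == {"wald"}
        assert res.q is None
        wald = wald_ratio(0.2, 0.01, 0.06, 0.05)
        assert res.primary.beta == pytest.approx(wald.beta)
        assert res.primary.se == pytest.approx(wald.se)

    def test_two_instruments_no_egger(self):
        res = mr_auto(make_harmonized([0.1, 0.2], [0.05, 0.1]))
        assert set(res.estimates) == {"ivw"}
        assert res.q is not None

    def test_five_proportional_instruments_all_methods_agree(self, proportional_data):
        res = mr_auto(proportional_data, n_boot=20, seed=0)
        assert set(res.estimates) == {"ivw", "egger", "weighted_median",
                                      "weighted_mode"}
        for est in res.estimates.values():
            assert est.beta == pytest.approx(0.5, abs=0.01)
        assert res.q.q == pytest.approx(0.0, abs=1e-20)

    def test_empty_dataset_raises(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_auto(make_harmonized([], []))


def test_sign_equivariance_of_all_estimators():
    """Negating every outcome effect negates every beta and preserves
    every SE, Q and p-value."""
    rng = np.random.default_rng(3)
    bx = rng.uniform(0.05, 0.4, 8)
    by = 0.3 * bx + rng.normal(0, 0.02, 8)
    byse = rng.uniform(0.01, 0.05, 8)
    pos = make_harmonized(bx, by, byse=byse)
    neg = make_harmonized(bx, -by, byse=byse)
    res_p = mr_auto(pos, n_boot=200, seed=1)
    res_n = mr_auto(neg, n_boot=200, seed=1)
    for name in res_p.estimates:
        ep, en = res_p.estimates[name], res_n.estimates[name]
        assert ep.beta == pytest.approx(-en.beta, abs=1e-9)
        if name in ("ivw", "egger"):
            # analytic SEs are exactly sign-invariant; bootstrap SEs only
            # up to resampling error
            assert ep.se == pytest.approx(en.se, rel=1e-9)
            assert ep.pval == pytest.approx(en.pval, rel=1e-6)
        else:
            assert ep.se == pytest.approx(en.se, rel=0.3)
    assert res_p.q.q == pytest.approx(res_n.q.q)
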