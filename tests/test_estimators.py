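import dataclasses
import math

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from adipomr.estimators import (
    cochran_q,
    estimate_survival,
    ivw_fixed_effects,
    mr_egger,
    wald_ratio,
)
from adipomr.exceptions import (
    CollinearInstrumentsError,
    DegenerateInstrumentError,
    EstimationInputError,
    InsufficientInstrumentsError,
)
from adipomr.records import OutcomeScale

from conftest import make_pair, random_pairs


def wls_through_origin(bx, by, sy):
    """Independent oracle: weighted least squares of by on bx through the
    origin, weights 1/sy^2, solved via the scaled normal equations."""
    sw = 1.0 / sy
    slope, *_ = np.linalg.lstsq((bx * sw)[:, None], by * sw, rcond=None)
    return float(slope[0])


class TestWaldRatio:
    def test_direct_arithmetic(self):
        ratio, se = wald_ratio(make_pair(beta_x=0.10, beta_y=0.05, se_y=0.02))
        assert ratio == pytest.approx(0.5)
        assert se == pytest.approx(0.2)

    def test_negative_exposure_effect_flips_sign_not_se(self):
        ratio, se = wald_ratio(make_pair(beta_x=-0.10, beta_y=0.05, se_y=0.02))
        assert ratio == pytest.approx(-0.5)
        assert se == pytest.approx(0.2)

    def test_zero_exposure_effect_is_an_error(self):
        with pytest.raises(DegenerateInstrumentError, match="rs1"):
            wald_ratio(make_pair(beta_x=0.0))

    def test_second_order_se_adds_exposure_uncertainty(self):
        pair = make_pair(beta_x=0.1, se_x=0.02, beta_y=0.05, se_y=0.02)
        _, se1 = wald_ratio(pair)
        _, se2 = wald_ratio(pair, second_order=True)
        expected = math.sqrt(0.02**2 / 0.1**2 + 0.05**2 * 0.02**2 / 0.1**4)
        assert se2 == pytest.approx(expected, rel=1e-12)
        assert se2 > se1


class TestIVW:
    def test_single_pair_reduces_to_wald_ratio(self):
        pair = make_pair(beta_x=0.08, beta_y=0.03, se_y=0.04)
        est = ivw_fixed_effects([pair])
        ratio, se = wald_ratio(pair)
        assert est.beta_hat == pytest.approx(ratio, abs=0)
        assert est.se_hat == pytest.approx(se, abs=0)
        assert est.n_snps == 1

    def test_two_identical_design_pairs_average_the_ratios(self):
        p1 = make_pair(snp="rs1", beta_x=0.1, beta_y=0.04, se_y=0.05)
        p2 = make_pair(snp="rs2", beta_x=0.1, beta_y=0.06, se_y=0.05)
        est = ivw_fixed_effects([p1, p2])
        assert est.beta_hat == pytest.approx((0.4 + 0.6) / 2, rel=1e-12)

    def test_matches_wls_oracle_and_statsmodels(self, rng):
        pairs = random_pairs(rng, 20)
        bx = np.array([p.beta_x for p in pairs])
        by = np.array([p.beta_y for p in pairs])
        sy = np.array([p.se_y for p in pairs])
        est = ivw_fixed_effects(pairs)
        assert est.beta_hat == pytest.approx(wls_through_origin(bx, by, sy), rel=1e-10)
        sm_fit = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
        assert est.beta_hat == pytest.approx(float(sm_fit.params[0]), rel=1e-10)

    def test_ci_uses_the_95_normal_multiplier(self, rng):
        est = ivw_fixed_effects(random_pairs(rng, 10))
        assert est.ci_low == pytest.approx(math.exp(est.beta_hat - 1.959964 * est.se_hat))
        assert est.ci_high == pytest.approx(math.exp(est.beta_hat + 1.959964 * est.se_hat))
        assert est.ci_low < est.ratio_scale < est.ci_high

    def test_scale_equivariance_in_exposure_units(self, rng):
        pairs = random_pairs(rng, 15)
        scaled = [dataclasses.replace(p, beta_x=3.0 * p.beta_x) for p in pairs]
        a, b = ivw_fixed_effects(pairs), ivw_fixed_effects(scaled)
        assert b.beta_hat == pytest.approx(a.beta_hat / 3.0, rel=1e-12)
        assert b.se_hat == pytest.approx(a.se_hat / 3.0, rel=1e-12)

    def test_sign_equivariance_in_outcome(self, rng):
        pairs = random_pairs(rng, 15)
        negated = [dataclasses.replace(p, beta_y=-p.beta_y) for p in pairs]
        a, b = ivw_fixed_effects(pairs), ivw_fixed_effects(negated)
        assert b.beta_hat == pytest.approx(-a.beta_hat, rel=1e-12)
        assert b.se_hat == a.se_hat
        assert b.pvalue == pytest.approx(a.pvalue, rel=1e-12)

    def test_empty_and_mixed_cohort_inputs_are_errors(self, rng):
        with pytest.raises(EstimationInputError):
            ivw_fixed_effects([])
        mixed = random_pairs(rng, 3, cohort="UK") + random_pairs(rng, 3, cohort="DE")
        with pytest.raises(EstimationInputError, match="cohorts"):
            ivw_fixed_effects(mixed)

    def test_zero_exposure_effect_names_the_snp(self):
        pairs = [make_pair(snp="rs7", beta_x=0.0), make_pair(snp="rs8")]
        with pytest.raises(DegenerateInstrumentError, match="rs7"):
            ivw_fixed_effects(pairs)


class TestSurvival:
    def test_same_numbers_different_scale_label(self, rng):
        odds = random_pairs(rng, 12, scale=OutcomeScale.LOG_ODDS)
        hazard = [dataclasses.replace(p, outcome_scale=OutcomeScale.LOG_HAZARD) for p in odds]
        a = ivw_fixed_effects(odds)
        b = estimate_survival(hazard)
        assert b.beta_hat == a.beta_hat
        assert b.se_hat == a.se_hat
        assert b.outcome_scale.ratio_label == "HR"

    def test_rejects_log_odds_pairs(self, rng):
        with pytest.raises(EstimationInputError):
            estimate_survival(random_pairs(rng, 5, scale=OutcomeScale.LOG_ODDS))


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.05, 0.08, 0.11, 0.14, 0.20])
        sy = np.array([0.03, 0.05, 0.02, 0.04, 0.06])
        pairs = [
            make_pair(snp=f"rs{i}", beta_x=float(b), beta_y=float(0.1 + 0.3 * b), se_y=float(s))
            for i, (b, s) in enumerate(zip(bx, sy))
        ]
        res = mr_egger(pairs)
        assert res.intercept == pytest.approx(0.1, abs=1e-10)
        assert res.slope == pytest.approx(0.3, abs=1e-10)
        assert res.df == 3

    def test_matches_statsmodels_wls_with_dispersion_floor(self, rng):
        pairs = random_pairs(rng, 25)
        bx = np.abs(np.array([p.beta_x for p in pairs]))
        by = np.array([p.beta_y for p in pairs]) * np.sign([p.beta_x for p in pairs])
        sy = np.array([p.se_y for p in pairs])
        res = mr_egger(pairs)
        sm_fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        assert res.intercept == pytest.approx(float(sm_fit.params[0]), rel=1e-10)
        assert res.slope == pytest.approx(float(sm_fit.params[1]), rel=1e-10)
        # statsmodels uses the estimated dispersion; ours is floored at 1
        adjust = math.sqrt(max(1.0, sm_fit.scale) / sm_fit.scale)
        assert res.se_slope == pytest.approx(float(sm_fit.bse[1]) * adjust, rel=1e-10)
        assert res.se_intercept == pytest.approx(float(sm_fit.bse[0]) * adjust, rel=1e-10)

    def test_zero_intercept_fit_equals_ivw_slope(self, rng):
        """Algebraic identity: when the fitted intercept is exactly zero the
        Egger slope coincides with the IVW (through-origin) slope."""
        pairs = random_pairs(rng, 30)
        pairs = [dataclasses.replace(p, beta_x=abs(p.beta_x)) for p in pairs]
        first = mr_egger(pairs)
        shifted = [dataclasses.replace(p, beta_y=p.beta_y - first.intercept) for p in pairs]
        second = mr_egger(shifted)
        assert second.intercept == pytest.approx(0.0, abs=1e-12)
        ivw = ivw_fixed_effects(shifted)
        assert second.slope == pytest.approx(ivw.beta_hat, rel=1e-10)

    def test_orientation_invariance(self, rng):
        pairs = random_pairs(rng, 20)
        flipped = [
            dataclasses.replace(p, beta_x=-p.beta_x, beta_y=-p.beta_y)
            if i % 3 == 0
            else p
            for i, p in enumerate(pairs)
        ]
        a, b = mr_egger(pairs), mr_egger(flipped)
        assert b.slope == pytest.approx(a.slope, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_too_few_instruments(self, rng):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(random_pairs(rng, 2))

    def test_collinear_exposure_effects(self):
        pairs = [make_pair(snp=f"rs{i}", beta_x=0.1, beta_y=0.01 * i) for i in range(3)]
        with pytest.raises(CollinearInstrumentsError):
            mr_egger(pairs)


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        pairs = [
            make_pair(snp=f"rs{i}", beta_x=b, beta_y=0.4 * b, se_y=0.02)
            for i, b in enumerate([0.05, 0.1, 0.2])
        ]
        res = cochran_q(pairs, ivw_fixed_effects(pairs))
        assert res.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert res.p_het == pytest.approx(1.0)

    def test_hand_computed_two_snp_example(self):
        # equal unit weights (beta_x = se_y) and ratios 0.5, 1.5:
        # pooled ratio 1, Q = 1*(0.5-1)^2 + 1*(1.5-1)^2 = 0.5
        pairs = [
            make_pair(snp="rs1", beta_x=0.1, beta_y=0.05, se_y=0.1),
            make_pair(snp="rs2", beta_x=0.1, beta_y=0.15, se_y=0.1),
        ]
        res = cochran_q(pairs, ivw_fixed_effects(pairs))
        assert res.q_statistic == pytest.approx(0.5, rel=1e-12)
        assert res.df == 1
        assert res.p_het == pytest.approx(float(stats.chi2.sf(0.5, 1)), rel=1e-12)

    def test_null_p_values_are_uniform(self):
        """Under a homogeneous causal model the Q p-values are U(0,1)."""
        rng = np.random.default_rng(7)
        n_reps, j = 1000, 20
        pvals = np.empty(n_reps)
        for r in range(n_reps):
            bx = rng.uniform(0.05, 0.15, j)
            sy = rng.uniform(0.02, 0.08, j)
            by = 0.2 * bx + rng.normal(0.0, sy)
            pairs = [
                make_pair(snp=f"rs{i}", beta_x=float(bx[i]), beta_y=float(by[i]),
                          se_y=float(sy[i]))
                for i in range(j)
            ]
            pvals[r] = cochran_q(pairs, ivw_fixed_effects(pairs)).p_het
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_mismatched_estimate_is_an_error(self, rng):
        pairs = random_pairs(rng, 5)
        other = ivw_fixed_effects(random_pairs(rng, 4))
        with pytest.raises(EstimationInputError):
            cochran_q(pairs, other)
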