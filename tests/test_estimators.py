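"""Causal estimators: Wald ratio, IVW, MR-Egger, weighted median."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mrscreen.estimators import (
    _weighted_median,
    ivw,
    ivw_fixed_effect,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from mrscreen.harmonize import HarmonizedInstrument, HarmonizedSet

from conftest import make_harmonized


def _inst(bx, by, se_out, se_exp=0.05, snp_id="rs1"):
    return HarmonizedInstrument(snp_id, bx, se_exp, by, se_out)


def _set(triples, exposure_id="genus.X"):
    return HarmonizedSet.from_instruments(
        exposure_id,
        [_inst(bx, by, se, snp_id=f"rs{i}") for i, (bx, by, se) in enumerate(triples)],
    )


class TestWaldRatio:
    def test_ratio_arithmetic(self):
        est = wald_ratio(_inst(0.5, 0.25, 0.1))
        assert est.beta == pytest.approx(0.5)

    def test_null_outcome_gives_or_one(self):
        est = wald_ratio(_inst(0.5, 0.0, 0.1))
        assert est.beta == 0.0 and est.or_ == 1.0

    def test_delta_method_se(self):
        est = wald_ratio(_inst(0.5, 0.25, 0.1))
        assert est.se == pytest.approx(0.1 / 0.5)
        est_neg = wald_ratio(_inst(-0.5, 0.25, 0.1))
        assert est_neg.se == pytest.approx(0.2)  # |beta_exp| in the denominator

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(ValueError):
            wald_ratio(_inst(0.0, 0.25, 0.1))


class TestIVW:
    def test_worked_two_instrument_example(self, two_instrument_set):
        est = ivw(two_instrument_set)
        assert est.beta == pytest.approx(5.3 / 26, abs=1e-12)
        fixed = ivw_fixed_effect(two_instrument_set)
        assert fixed.se == pytest.approx(26 ** -0.5, abs=1e-12)

    def test_identical_ratios_recover_ratio_exactly(self):
        r = 0.37
        h = _set([(bx, r * bx, 0.1) for bx in (0.2, 0.4, 0.6)])
        est = ivw(h)
        assert est.beta == pytest.approx(r, abs=1e-14)
        # Q = 0 so random-effects SE equals the fixed-effect SE
        assert est.se == pytest.approx(ivw_fixed_effect(h).se, abs=1e-14)

    def test_single_instrument_rejected_toward_wald(self):
        h = _set([(0.5, 0.1, 0.1)])
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(h)

    def test_wald_is_ivw_limit_of_vanishing_second_weight(self):
        strong = _inst(0.5, 0.12, 0.1, snp_id="rs_a")
        feeble = _inst(0.3, 0.40, 1e6, snp_id="rs_b")  # weight -> 0
        est = ivw(HarmonizedSet.from_instruments("x", [strong, feeble]))
        assert est.beta == pytest.approx(wald_ratio(strong).beta, rel=1e-9)

    def test_random_effects_se_never_below_fixed(self, rng):
        for _ in range(20):
            h = make_harmonized(rng, k=8, se_out=0.2)
            assert ivw(h).se >= ivw_fixed_effect(h).se - 1e-15


class TestEgger:
    def test_exact_linear_relation_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.03 + 0.4 * bx
        h = _set(list(zip(bx, by, [0.1] * 5)))
        est, intercept = mr_egger(h)
        assert est.beta == pytest.approx(0.4, abs=1e-12)
        assert intercept.intercept == pytest.approx(0.03, abs=1e-12)
        # exact fit: residual variance floored at 1, so SEs are the
        # classical equal-weight regression SEs with sigma = se_out
        sxx = np.sum((bx - bx.mean()) ** 2)
        assert est.se == pytest.approx(0.1 / math.sqrt(sxx), rel=1e-10)

    def test_orientation_convention_makes_result_sign_stable(self, rng):
        h = make_harmonized(rng, k=10)
        est1, int1 = mr_egger(h)
        # negate both betas of some instruments: same oriented data
        df = h.df.copy()
        flip = np.array([1, -1, 1, -1, 1, 1, -1, 1, 1, -1], dtype=float)
        df["beta_exp"] *= flip
        df["beta_out"] *= flip
        est2, int2 = mr_egger(HarmonizedSet(h.exposure_id, df))
        assert est2.beta == pytest.approx(est1.beta, abs=1e-12)
        assert int2.intercept == pytest.approx(int1.intercept, abs=1e-12)

    def test_too_few_or_degenerate_instruments_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(_set([(0.5, 0.1, 0.1), (0.2, 0.06, 0.2)]))
        with pytest.raises(ValueError, match="variance"):
            mr_egger(_set([(0.3, 0.1, 0.1)] * 4))


class TestWeightedMedian:
    def test_equal_weight_median(self):
        h = _set([(1.0, 0.1, 0.1), (1.0, 0.2, 0.1), (1.0, 0.3, 0.1)])
        est = weighted_median(h, n_boot=10, seed=0)
        assert est.beta == pytest.approx(0.2, abs=1e-12)

    def test_dominant_weight_pins_estimate_near_its_ratio(self):
        # first SNP carries ~96% of the weight
        h = _set([(1.0, 0.50, 0.1), (0.2, 0.02, 0.1), (0.2, 0.06, 0.1)])
        est = weighted_median(h, n_boot=10, seed=0)
        theta = np.sort([0.5, 0.1, 0.3])
        lo, hi = theta[1], theta[2]  # interpolation neighbourhood of 0.5
        assert lo <= est.beta <= hi
        assert est.beta == pytest.approx(0.5, abs=0.05)

    def test_interpolation_with_uneven_weights(self):
        # hand-computed: ratios (0,1,2), weights (0.4,0.4,0.2)
        # midpoints s = (0.2, 0.6, 0.9); interpolate 0.5 -> 0.75
        est = _weighted_median(np.array([0.0, 1.0, 2.0]), np.array([0.4, 0.4, 0.2]))
        assert est == pytest.approx(0.75, abs=1e-12)

    def test_zero_beta_exp_dropped_with_remainder_used(self, rng):
        h = _set([(0.0, 0.1, 0.1), (1.0, 0.2, 0.1), (1.0, 0.4, 0.1)])
        est = weighted_median(h, n_boot=10, seed=0)
        assert est.n_snp == 2

    def test_bootstrap_reproducible_under_seed(self, rng):
        h = make_harmonized(rng, k=10)
        a = weighted_median(h, n_boot=100, seed=7)
        b = weighted_median(h, n_boot=100, seed=7)
        assert a.se == b.se


class TestEquivariance:
    @pytest.fixture
    def h(self, rng):
        return make_harmonized(rng, k=12, theta=0.25)

    def _fit_all(self, h):
        return {
            "ivw": ivw(h).beta,
            "mr_egger": mr_egger(h)[0].beta,
            "weighted_median": weighted_median(h, n_boot=10, seed=0).beta,
        }

    def test_negating_outcome_negates_all_estimates_and_inverts_or(self, h):
        base = self._fit_all(h)
        df = h.df.copy()
        df["beta_out"] = -df["beta_out"]
        flipped = self._fit_all(HarmonizedSet(h.exposure_id, df))
        for method in base:
            assert flipped[method] == pytest.approx(-base[method], rel=1e-9)
        assert ivw(HarmonizedSet(h.exposure_id, df)).or_ == pytest.approx(
            1.0 / ivw(h).or_, rel=1e-9
        )

    @given(c=st.floats(0.1, 10))
    def test_scaling_exposure_divides_estimates(self, c):
        rng = np.random.default_rng(77)
        h = make_harmonized(rng, k=12, theta=0.25)
        base = self._fit_all(h)
        df = h.df.copy()
        df["beta_exp"] *= c
        df["se_exp"] *= c
        scaled = self._fit_all(HarmonizedSet(h.exposure_id, df))
        for method in base:
            assert scaled[method] == pytest.approx(base[method] / c, rel=1e-9)

    def test_ci_bounds_symmetric_about_log_or(self, h):
        for est in (ivw(h), mr_egger(h)[0], weighted_median(h, n_boot=50, seed=0)):
            lo, hi = math.log(est.ci_low), math.log(est.ci_high)
            assert (lo + hi) / 2 == pytest.approx(est.beta, rel=1e-9)
            assert est.ci_low < est.or_ < est.ci_high
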