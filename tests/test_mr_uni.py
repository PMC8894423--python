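"""Univariable MR estimators against independent oracles and closed forms."""

import numpy as np
import pytest
from scipy import stats

from mrdt.exceptions import EstimationError
from mrdt.mr_uni import (
    cochran_q,
    i2gx,
    ivw,
    ivw_correlated,
    mr_egger,
    wald_ratio,
    wald_ratio_se2,
    weighted_median,
)
from mrdt.sumstats import LDMatrix

from conftest import h_from_arrays


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        h = h_from_arrays([0.1], [0.01], [0.2], [0.05])
        est = wald_ratio(h)
        assert est.beta == pytest.approx(2.0)
        assert est.se == pytest.approx(0.5)

    def test_negative_exposure_effect(self):
        h = h_from_arrays([-0.1], [0.01], [0.2], [0.05])
        assert wald_ratio(h).beta == pytest.approx(-2.0)

    def test_null_instrument_is_error(self):
        h = h_from_arrays([0.0], [0.01], [0.2], [0.05])
        with pytest.raises(EstimationError, match="null instrument"):
            wald_ratio(h)

    def test_second_order_se_matches_monte_carlo(self):
        bx, sx, by, sy = 0.5, 0.02, 0.3, 0.04
        h = h_from_arrays([bx], [sx], [by], [sy])
        se2 = wald_ratio_se2(h)
        rng = np.random.default_rng(7)
        n = 1_000_000
        draws = rng.normal(by, sy, n) / rng.normal(bx, sx, n)
        assert se2 == pytest.approx(np.std(draws), rel=0.02)


class TestIVW:
    def test_single_snp_reduces_to_wald(self):
        h = h_from_arrays([0.2], [0.01], [0.1], [0.03])
        w, i = wald_ratio(h), ivw(h)
        assert i.beta == pytest.approx(w.beta) and i.se == pytest.approx(w.se)

    def test_duplicated_snp_halves_variance(self):
        h1 = h_from_arrays([0.2], [0.01], [0.1], [0.03])
        h2 = h_from_arrays([0.2, 0.2], [0.01, 0.01], [0.1, 0.1], [0.03, 0.03])
        e1, e2 = ivw(h1), ivw(h2)
        assert e2.beta == pytest.approx(e1.beta)
        assert e2.se == pytest.approx(e1.se / np.sqrt(2))  # Q=0 so scale stays 1

    def test_matches_weighted_regression_through_origin(self, seeded_h):
        est = ivw(seeded_h)
        bx, by, sy = (seeded_h.beta_exposure, seeded_h.beta_outcome,
                      seeded_h.se_outcome)
        # independent oracle: sqrt-weight transformed least squares
        sw = 1.0 / sy
        coef, res, *_ = np.linalg.lstsq((sw * bx)[:, None], sw * by, rcond=None)
        k = seeded_h.k
        q = float(res[0])
        se_fixed = 1.0 / np.sqrt(np.sum((bx / sy) ** 2))
        se = se_fixed * max(1.0, np.sqrt(q / (k - 1)))
        assert est.beta == pytest.approx(float(coef[0]), abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)
        assert est.q_statistic == pytest.approx(q, abs=1e-10)

    def test_multiplicative_scale_never_shrinks_se(self, seeded_h):
        assert ivw(seeded_h).se >= ivw(seeded_h, effects_model="fixed").se


class TestIVWCorrelated:
    def test_identity_ld_equals_plain_ivw(self, seeded_h):
        ld = LDMatrix(seeded_h.rsids, np.eye(seeded_h.k))
        a, b = ivw_correlated(seeded_h, ld), ivw(seeded_h)
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)

    def test_duplicated_information_adds_none(self):
        single = h_from_arrays([0.2], [0.01], [0.1], [0.03])
        double = h_from_arrays([0.2, 0.2], [0.01, 0.01], [0.1, 0.1], [0.03, 0.03])
        rho = 0.999
        ld = LDMatrix(double.rsids, np.array([[1.0, rho], [rho, 1.0]]))
        est = ivw_correlated(double, ld)
        ref = wald_ratio(single)
        assert est.beta == pytest.approx(ref.beta, abs=1e-6)
        assert est.se == pytest.approx(ref.se, rel=1e-3)

    def test_matches_explicit_gls_oracle(self):
        rng = np.random.default_rng(21)
        k = 6
        base = rng.uniform(0.13, 0.9)
        rho = np.full((k, k), base)
        np.fill_diagonal(rho, 1.0)
        bx = rng.uniform(0.1, 0.3, k)
        sy = rng.uniform(0.01, 0.05, k)
        by = 0.4 * bx + rng.normal(0, 0.02, k)
        h = h_from_arrays(bx, bx * 0 + 0.01, by, sy)
        ld = LDMatrix(h.rsids, rho)
        est = ivw_correlated(h, ld)
        omega_inv = np.linalg.inv(np.outer(sy, sy) * rho)
        beta = (bx @ omega_inv @ by) / (bx @ omega_inv @ bx)
        resid = by - beta * bx
        q = resid @ omega_inv @ resid
        se = (bx @ omega_inv @ bx) ** -0.5 * max(1.0, np.sqrt(q / (k - 1)))
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_near_singular_ld_is_error(self):
        h = h_from_arrays([0.2, 0.2], [0.01, 0.01], [0.1, 0.1], [0.03, 0.03])
        rho = np.array([[1.0, 1.0 - 1e-12], [1.0 - 1e-12, 1.0]])
        ld = LDMatrix(h.rsids, rho)
        with pytest.raises(EstimationError, match="near-singular"):
            ivw_correlated(h, ld)


class TestMREgger:
    def test_exact_line_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.5 + 2.0 * bx
        h = h_from_arrays(bx, bx * 0 + 0.01, by, bx * 0 + 0.02)
        est = mr_egger(h)
        assert est.beta == pytest.approx(2.0, abs=1e-12)
        assert est.egger_intercept == pytest.approx(0.5, abs=1e-12)
        assert est.q_statistic == pytest.approx(0.0, abs=1e-10)

    def test_constant_exposure_effects_error(self):
        h = h_from_arrays([0.2] * 3, [0.01] * 3, [0.1, 0.2, 0.3], [0.02] * 3)
        with pytest.raises(EstimationError, match="collinear"):
            mr_egger(h)

    def test_too_few_snps_error(self):
        h = h_from_arrays([0.1, 0.2], [0.01] * 2, [0.1, 0.2], [0.02] * 2)
        with pytest.raises(EstimationError, match="k ≥ 3"):
            mr_egger(h)

    def test_matches_statsmodels_wls_oracle(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(5)
        k = 8
        bx = rng.uniform(0.1, 0.4, k)
        sy = rng.uniform(0.01, 0.05, k)
        by = 0.05 + 0.7 * bx + rng.normal(0, 0.3, k)  # heterogeneous: Q/df > 1
        h = h_from_arrays(bx, bx * 0 + 0.01, by, sy)
        est = mr_egger(h)
        fit = sm.WLS(by, sm.add_constant(bx), weights=1.0 / sy**2).fit()
        q = float(np.sum((1.0 / sy**2) * fit.resid**2))
        assert q / (k - 2) > 1.0  # statsmodels' estimated scale == our inflation
        assert est.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert est.egger_intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert est.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert est.intercept_se == pytest.approx(fit.bse[0], abs=1e-10)

    def test_egger_equals_ivw_when_intercept_zero(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 2.0 * bx
        h = h_from_arrays(bx, bx * 0 + 0.01, by, bx * 0 + 0.02)
        assert mr_egger(h).beta == pytest.approx(ivw(h).beta, abs=1e-12)


class TestI2GX:
    def test_zero_when_qgx_equals_dof(self):
        # k=2, equal unit weights, |bx| gap sqrt(2) -> Q_GX = 1 = k-1
        h = h_from_arrays([0.0 + 1e-300, np.sqrt(2)], [1.0, 1.0], [0, 0], [1, 1])
        assert i2gx(h) == pytest.approx(0.0, abs=1e-9)

    def test_limit_one_for_vanishing_exposure_se(self):
        h = h_from_arrays([0.1, 0.2, 0.3], [1e-8] * 3, [0, 0, 0], [1] * 3)
        assert i2gx(h) == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_formula(self, seeded_h):
        q = 1.0 / seeded_h.se_exposure**2
        bxa = np.abs(seeded_h.beta_exposure)
        bbar = np.sum(q * bxa) / np.sum(q)
        qgx = np.sum(q * (bxa - bbar) ** 2)
        expect = (qgx - (seeded_h.k - 1)) / qgx
        assert i2gx(seeded_h) == pytest.approx(expect, abs=1e-12)

    def test_unweighted_variant_uses_common_weight(self, seeded_h):
        q = 1.0 / np.mean(seeded_h.se_exposure**2)
        bxa = np.abs(seeded_h.beta_exposure)
        qgx = q * np.sum((bxa - np.mean(bxa)) ** 2)
        expect = (qgx - (seeded_h.k - 1)) / qgx
        assert i2gx(seeded_h, variant="unweighted") == pytest.approx(expect, abs=1e-12)


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        h = h_from_arrays([1, 1, 1], [0.01] * 3, [1, 2, 10], [1, 1, 1])
        est = weighted_median(h, bootstrap_iters=0)
        assert est.beta == pytest.approx(2.0)

    def test_majority_weight_snp_wins(self):
        # dominant weight (>0.5) on the middle-sorted ratio
        sy = np.array([1.0, 1.0 / np.sqrt(18), 1.0])  # weights 1/20, 18/20, 1/20
        h = h_from_arrays([1, 1, 1], [0.01] * 3, [1.0, 2.0, 10.0], sy)
        est = weighted_median(h, bootstrap_iters=0)
        assert est.beta == pytest.approx(2.0)

    def test_bootstrap_se_reproducible(self):
        rng = np.random.default_rng(9)
        bx = rng.uniform(0.1, 0.3, 6)
        by = 0.5 * bx + rng.normal(0, 0.02, 6)
        h = h_from_arrays(bx, bx * 0 + 0.01, by, bx * 0 + 0.02)
        a = weighted_median(h, bootstrap_iters=500, seed=4)
        b = weighted_median(h, bootstrap_iters=500, seed=4)
        assert a.se == b.se and np.isfinite(a.se)


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        h = h_from_arrays([0.1, 0.2], [0.01] * 2, [0.2, 0.4], [0.02] * 2)
        q, df, p = cochran_q(h)
        assert q == pytest.approx(0.0, abs=1e-12) and df == 1 and p == pytest.approx(1.0)

    def test_two_snp_closed_form(self):
        bx = np.array([0.1, 0.2])
        by = np.array([0.05, 0.3])
        sy = np.array([0.02, 0.03])
        h = h_from_arrays(bx, bx * 0 + 0.01, by, sy)
        r = by / bx
        w = bx**2 / sy**2
        expect = w[0] * w[1] * (r[0] - r[1]) ** 2 / (w[0] + w[1])
        q, df, _ = cochran_q(h)
        assert q == pytest.approx(expect, abs=1e-12)


@pytest.mark.parametrize("c", [2.0, -3.0, 0.5])
def test_scale_equivariance_of_all_estimators(seeded_h, c):
    """Multiplying exposure betas by c scales every causal estimate by 1/c."""
    scaled = h_from_arrays(
        c * seeded_h.beta_exposure,
        abs(c) * seeded_h.se_exposure,
        seeded_h.beta_outcome,
        seeded_h.se_outcome,
    )
    ld = LDMatrix(seeded_h.rsids, np.eye(seeded_h.k))
    for f in (
        ivw,
        lambda h: ivw_correlated(h, ld),
        mr_egger,
        lambda h: weighted_median(h, bootstrap_iters=0),
    ):
        assert f(scaled).beta == pytest.approx(f(seeded_h).beta / c, rel=1e-9)
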