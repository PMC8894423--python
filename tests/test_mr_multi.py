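"""Multivariable MR: MVMR-IVW/Egger, conditional F, modified Q."""

import numpy as np
import pytest

from mrdt.exceptions import EstimationError, ValidationError
from mrdt.instruments import InstrumentSet
from mrdt.mr_multi import (
    MVMRDataset,
    assemble_mvmr,
    conditional_f,
    modified_q,
    mvmr_egger,
    mvmr_ivw,
)
from mrdt.mr_uni import ivw
from mrdt.sumstats import LDMatrix

from conftest import h_from_arrays, make_table


def _dataset(seed=13, k=12, theta=(0.6, 0.5), noise=0.02):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.05, 0.4, (k, 2))
    SE = rng.uniform(0.005, 0.02, (k, 2))
    sy = rng.uniform(0.01, 0.05, k)
    by = X @ np.array(theta) + rng.normal(0, noise, k)
    return MVMRDataset(
        rsids=tuple(f"rs{i}" for i in range(k)),
        exposure_matrix=X,
        exposure_se_matrix=SE,
        beta_outcome=by,
        se_outcome=sy,
    )


class TestMVMRIVW:
    def test_null_second_exposure_reduces_to_univariable(self):
        rng = np.random.default_rng(1)
        k = 10
        bx = rng.uniform(0.1, 0.3, k)
        sy = rng.uniform(0.01, 0.04, k)
        by = 0.5 * bx + rng.normal(0, 0.02, k)
        # machine-scale second column carrying no explanatory direction:
        # orthogonal (in the weight metric) to both the exposure and outcome
        w = 1.0 / sy**2
        by_perp = by - bx * np.sum(w * by * bx) / np.sum(w * bx * bx)
        v = rng.normal(0, 1.0, k)
        for u in (bx, by_perp):  # W-orthogonal basis of span{bx, by}
            v -= u * np.sum(w * v * u) / np.sum(w * u * u)
        x2 = 1e-9 * v
        d = MVMRDataset(
            rsids=tuple(f"rs{i}" for i in range(k)),
            exposure_matrix=np.column_stack([bx, x2]),
            exposure_se_matrix=np.full((k, 2), 0.01),
            beta_outcome=by,
            se_outcome=sy,
        )
        uni = ivw(h_from_arrays(bx, [0.01] * k, by, sy))
        assert mvmr_ivw(d).beta[0] == pytest.approx(uni.beta, abs=1e-6)

    def test_exact_linear_system_recovered(self):
        d = _dataset(noise=0.0)
        est = mvmr_ivw(d)
        np.testing.assert_allclose(est.beta, [0.6, 0.5], atol=1e-10)
        q, _, p = modified_q(d, est.beta)
        assert est.q_modified == pytest.approx(q)

    def test_matches_normal_equations_oracle(self):
        d = _dataset()
        est = mvmr_ivw(d)
        w = 1.0 / d.se_outcome**2
        sw = np.sqrt(w)
        coef, res, *_ = np.linalg.lstsq(
            sw[:, None] * d.exposure_matrix, sw * d.beta_outcome, rcond=None
        )
        q = float(res[0])
        cov = np.linalg.inv(d.exposure_matrix.T @ (w[:, None] * d.exposure_matrix))
        scale = max(1.0, np.sqrt(q / (d.k - d.L)))
        np.testing.assert_allclose(est.beta, coef, atol=1e-10)
        np.testing.assert_allclose(est.se, np.sqrt(np.diag(cov)) * scale, atol=1e-10)

    def test_collinear_exposures_error(self):
        rng = np.random.default_rng(2)
        x1 = rng.uniform(0.1, 0.3, 8)
        d = MVMRDataset(
            rsids=tuple(f"rs{i}" for i in range(8)),
            exposure_matrix=np.column_stack([x1, 2 * x1]),
            exposure_se_matrix=np.full((8, 2), 0.01),
            beta_outcome=x1,
            se_outcome=np.full(8, 0.02),
        )
        with pytest.raises(EstimationError, match="collinear"):
            mvmr_ivw(d)

    def test_single_exposure_equals_univariable_ivw(self, seeded_h):
        d = MVMRDataset(
            rsids=seeded_h.rsids,
            exposure_matrix=seeded_h.beta_exposure[:, None],
            exposure_se_matrix=seeded_h.se_exposure[:, None],
            beta_outcome=seeded_h.beta_outcome,
            se_outcome=seeded_h.se_outcome,
        )
        est, uni = mvmr_ivw(d), ivw(seeded_h)
        assert est.beta[0] == pytest.approx(uni.beta, abs=1e-12)
        assert est.se[0] == pytest.approx(uni.se, abs=1e-12)

    def test_row_permutation_invariance(self):
        d = _dataset()
        perm = np.random.default_rng(0).permutation(d.k)
        a, b = mvmr_ivw(d), mvmr_ivw(d.permuted(perm))
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-12)
        np.testing.assert_allclose(a.se, b.se, atol=1e-12)


class TestMVMREgger:
    def test_zero_pleiotropy_exact_system(self):
        d = _dataset(noise=0.0)
        est = mvmr_egger(d)
        assert est.egger_intercept == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(est.beta, mvmr_ivw(d).beta, atol=1e-8)

    def test_constant_outcome_shift_absorbed_by_intercept(self):
        d = _dataset(noise=0.0)
        shifted = MVMRDataset(
            rsids=d.rsids,
            exposure_matrix=d.exposure_matrix,
            exposure_se_matrix=d.exposure_se_matrix,
            beta_outcome=d.beta_outcome + 0.3,
            se_outcome=d.se_outcome,
        )
        # all exposure betas positive here, so no rows get sign-flipped
        est = mvmr_egger(shifted)
        assert est.egger_intercept == pytest.approx(0.3, abs=1e-10)
        np.testing.assert_allclose(est.beta, [0.6, 0.5], atol=1e-10)

    def test_matches_wls_oracle_with_intercept(self):
        d = _dataset(seed=8)
        est = mvmr_egger(d, orient_on=0)
        sign = np.where(d.exposure_matrix[:, 0] < 0, -1.0, 1.0)
        X = np.column_stack([np.ones(d.k), sign[:, None] * d.exposure_matrix])
        y = sign * d.beta_outcome
        w = 1.0 / d.se_outcome**2
        sw = np.sqrt(w)
        coef, res, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
        q = float(res[0])
        cov = np.linalg.inv(X.T @ (w[:, None] * X))
        scale = max(1.0, np.sqrt(q / (d.k - d.L - 1)))
        np.testing.assert_allclose(est.beta, coef[1:], atol=1e-10)
        np.testing.assert_allclose(
            est.se, np.sqrt(np.diag(cov))[1:] * scale, atol=1e-10
        )
        assert est.egger_intercept == pytest.approx(coef[0], abs=1e-10)

    def test_too_few_snps_error(self):
        d = _dataset(k=12)
        small = d.permuted(range(3))
        with pytest.raises(EstimationError, match="k ≥ L\\+2"):
            mvmr_egger(small)


class TestConditionalF:
    def test_null_other_exposure_matches_single_exposure_formula(self):
        rng = np.random.default_rng(4)
        k = 15
        x1 = rng.uniform(0.1, 0.3, k)
        se1 = rng.uniform(0.005, 0.02, k)
        x2 = np.zeros(k)  # no second-exposure signal at all
        d = MVMRDataset(
            rsids=tuple(f"rs{i}" for i in range(k)),
            exposure_matrix=np.column_stack([x1, x2]),
            exposure_se_matrix=np.column_stack([se1, se1]),
            beta_outcome=x1,
            se_outcome=np.full(k, 0.02),
        )
        got = conditional_f(d, 0)
        # same statistic computed with no conditioning exposures (L=1 form)
        expect = np.sum(x1**2 / se1**2) / (k - 2)
        assert got == pytest.approx(expect, rel=1e-9)

    def test_linearly_dependent_exposure_has_no_conditional_strength(self):
        rng = np.random.default_rng(6)
        k = 10
        x2 = rng.uniform(0.1, 0.3, k)
        x1 = 0.7 * x2
        d = MVMRDataset(
            rsids=tuple(f"rs{i}" for i in range(k)),
            exposure_matrix=np.column_stack([x1, x2]),
            exposure_se_matrix=np.full((k, 2), 0.01),
            beta_outcome=x2,
            se_outcome=np.full(k, 0.02),
        )
        assert conditional_f(d, 0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_reimplementation(self):
        d = _dataset(seed=19)
        for l in range(2):
            x = d.exposure_matrix[:, l]
            se = d.exposure_se_matrix[:, l]
            others = d.exposure_matrix[:, [1 - l]]
            w = 1.0 / se**2
            # explicit weighted projection
            a = float((others[:, 0] * w) @ x) / float((others[:, 0] * w) @ others[:, 0])
            q = float(np.sum(w * (x - a * others[:, 0]) ** 2))
            assert conditional_f(d, l) == pytest.approx(q / (d.k - d.L), rel=1e-10)

    def test_decreases_as_exposures_become_collinear(self):
        rng = np.random.default_rng(12)
        k = 40
        x2 = rng.uniform(0.1, 0.3, k)
        indep = rng.uniform(0.1, 0.3, k)
        fs = []
        for lam in (0.0, 0.4, 0.8, 0.95):
            x1 = lam * x2 + (1 - lam) * indep
            d = MVMRDataset(
                rsids=tuple(f"rs{i}" for i in range(k)),
                exposure_matrix=np.column_stack([x1, x2]),
                exposure_se_matrix=np.full((k, 2), 0.01),
                beta_outcome=x2,
                se_outcome=np.full(k, 0.02),
            )
            fs.append(conditional_f(d, 0))
        assert fs == sorted(fs, reverse=True)


class TestModifiedQ:
    def test_exact_system_with_tiny_ses(self):
        d = _dataset(noise=0.0)
        q, df, p = modified_q(d, (0.6, 0.5))
        assert q == pytest.approx(0.0, abs=1e-12)
        assert df == d.k - 2 and p == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        d = _dataset(seed=23)
        theta = np.array([0.55, 0.45])
        w = 1.0 / (d.se_outcome**2 + d.exposure_se_matrix**2 @ theta**2)
        resid = d.beta_outcome - d.exposure_matrix @ theta
        expect = float(np.sum(w * resid**2))
        q, df, _ = modified_q(d, theta)
        assert q == pytest.approx(expect, abs=1e-12)

    def test_theta_length_checked(self):
        d = _dataset()
        with pytest.raises(ValidationError):
            modified_q(d, (0.5,))


class TestAssembleMVMR:
    def _harmonized_union(self):
        k = 6
        rsids = ["rs12916", "rsB1", "rsB2", "rsB3", "rsB4", "rsB5"]
        rng = np.random.default_rng(31)
        h = h_from_arrays(
            rng.uniform(0.1, 0.3, k), [0.01] * k,
            rng.uniform(0.0, 0.2, k), [0.02] * k,
            bx2=rng.uniform(0.02, 0.08, k), sx2=[0.005] * k,
        )
        h.rsids = tuple(rsids)
        return h

    def test_ld_guard_removes_correlated_bmi_snp(self):
        h = self._harmonized_union()
        r = np.eye(6)
        r[0, 1] = r[1, 0] = np.sqrt(0.5)  # rsB1 in LD with rs12916
        ld = LDMatrix(h.rsids, r)
        d, log = assemble_mvmr(
            InstrumentSet("statins", ("rs12916",)),
            InstrumentSet("BMI", tuple(h.rsids[1:])),
            h, ld=ld, ld_guard_r2=0.001,
        )
        assert "rsB1" not in d.rsids and "rsB1" in log[0]
        assert d.k == 5

    def test_uncorrelated_sets_union(self):
        h = self._harmonized_union()
        d, log = assemble_mvmr(
            InstrumentSet("statins", ("rs12916",)),
            InstrumentSet("BMI", tuple(h.rsids[1:])),
            h, ld=None,
        )
        assert d.k == 6 and log == []
        assert d.rsids[0] == "rs12916"
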