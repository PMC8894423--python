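"""Univariable two-sample MR estimators and pleiotropy diagnostics.

All estimators operate on a :class:`~mrdt.sumstats.HarmonizedDataset` and
are written directly from their defining formulas:

* Wald ratio — per-SNP causal estimate by/bx with first-order delta SE.
* IVW — inverse-variance-weighted combination of Wald ratios, equivalent
  to weighted regression of by on bx through the origin; multiplicative
  random effects inflate the SE by max(1, sqrt(Q/(k−1))).
* Correlated-instrument IVW — generalized least squares with the outcome
  error covariance Ω_jk = se_yj · se_yk · ρ_jk built from a signed LD
  matrix.
* MR-Egger — weighted regression with intercept after orienting all
  exposure effects nonnegative; the intercept estimates average
  directional pleiotropy under the InSiDE assumption, and I²GX gauges the
  NOME assumption (values below 0.90 signal attenuation toward the null).
* Weighted median — consistent when more than half of the weight comes
  from valid instruments; SE by parametric bootstrap.

P-values use the normal reference throughout, the usual summary-data
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EstimationError
from .sumstats import HarmonizedDataset, LDMatrix

__all__ = [
    "MREstimate",
    "wald_ratio",
    "ivw",
    "ivw_correlated",
    "mr_egger",
    "i2gx",
    "weighted_median",
    "cochran_q",
]

Z95 = float(stats.norm.ppf(0.975))

#: condition-number guard for the GLS weight matrix
MAX_OMEGA_CONDITION = 1e8


@dataclass
class MREstimate:
    """A causal-effect estimate with its diagnostics.

    ``beta`` is on the log-odds scale for binary outcomes (exponentiate
    for an OR) or in outcome trait units otherwise.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    k: int
    q_statistic: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    p_intercept: float | None = None
    i2gx: float | None = None
    or_scale: bool = False

    def odds_ratio(self) -> tuple[float, float, float]:
        """(OR, ci_low, ci_high) by exponentiation."""
        return float(np.exp(self.beta)), float(np.exp(self.ci_low)), float(
            np.exp(self.ci_high)
        )

    def oriented(self, sign: float) -> "MREstimate":
        """Estimate for the sign-flipped exposure (e.g. per unit *decrease*)."""
        if sign not in (1.0, -1.0, 1, -1):
            raise ValueError("sign must be ±1")
        if sign == 1:
            return self
        out = MREstimate(**vars(self))
        out.beta = -self.beta
        out.ci_low = -self.ci_high
        out.ci_high = -self.ci_low
        if self.egger_intercept is not None:
            out.egger_intercept = -self.egger_intercept
        return out


def _finalize(method: str, beta: float, se: float, k: int, **extra) -> MREstimate:
    z = beta / se
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        pvalue=float(2.0 * stats.norm.sf(abs(z))),
        k=k,
        **extra,
    )


def _check_nonnull(bx: np.ndarray) -> None:
    if np.any(bx == 0):
        raise EstimationError("null instrument: zero exposure effect")


def wald_ratio(h: HarmonizedDataset) -> MREstimate:
    """Single-SNP causal estimate by/bx with first-order delta SE se_y/|bx|."""
    if h.k != 1:
        raise EstimationError(f"wald_ratio needs exactly one SNP, got {h.k}")
    bx = float(h.beta_exposure[0])
    if bx == 0:
        raise EstimationError("null instrument: zero exposure effect")
    beta = float(h.beta_outcome[0]) / bx
    se = float(h.se_outcome[0]) / abs(bx)
    return _finalize("wald", beta, se, 1)


def wald_ratio_se2(h: HarmonizedDataset) -> float:
    """Second-order delta SE of the single-SNP ratio (adds the exposure
    sampling-error term by²·se_x²/bx⁴)."""
    if h.k != 1:
        raise EstimationError("second-order SE is defined for a single SNP")
    bx, by = float(h.beta_exposure[0]), float(h.beta_outcome[0])
    sx, sy = float(h.se_exposure[0]), float(h.se_outcome[0])
    if bx == 0:
        raise EstimationError("null instrument: zero exposure effect")
    return float(np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4))


def _ivw_core(bx, by, sy):
    r = by / bx
    w = bx**2 / sy**2
    beta = float(np.sum(w * r) / np.sum(w))
    q = float(np.sum(w * (r - beta) ** 2))
    se_fixed = float(np.sum(w)) ** -0.5
    return r, w, beta, q, se_fixed


def ivw(h: HarmonizedDataset, effects_model: str = "multiplicative") -> MREstimate:
    """Inverse-variance-weighted estimate over k Wald ratios.

    Weighted regression of by on bx through the origin with weights
    1/se_y²; with the (default) multiplicative random-effects model the
    fixed-effect SE is inflated by max(1, sqrt(Q/(k−1))), never shrunk.
    """
    if effects_model not in ("multiplicative", "fixed"):
        raise ValueError(f"unknown effects model: {effects_model!r}")
    if h.k == 0:
        raise EstimationError("no instruments")
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    _check_nonnull(bx)
    _, _, beta, q, se_fixed = _ivw_core(bx, by, sy)
    scale = 1.0
    q_p = None
    if h.k >= 2:
        q_p = float(stats.chi2.sf(q, h.k - 1))
        if effects_model == "multiplicative":
            scale = max(1.0, np.sqrt(q / (h.k - 1)))
    return _finalize(
        "ivw",
        beta,
        se_fixed * scale,
        h.k,
        q_statistic=q if h.k >= 2 else None,
        q_pvalue=q_p,
    )


def ivw_correlated(
    h: HarmonizedDataset, ld: LDMatrix, effects_model: str = "multiplicative"
) -> MREstimate:
    """Generalized IVW for correlated instruments.

    GLS with Ω_jk = se_yj·se_yk·ρ_jk: beta = (bxᵀΩ⁻¹bx)⁻¹ bxᵀΩ⁻¹ by,
    fixed SE (bxᵀΩ⁻¹bx)^(−1/2), heterogeneity from the GLS residual
    quadratic form.  Reduces exactly to :func:`ivw` for identity LD.
    """
    if h.k == 0:
        raise EstimationError("no instruments")
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    _check_nonnull(bx)
    rho = ld.submatrix(h.rsids).r
    omega = np.outer(sy, sy) * rho
    if np.linalg.cond(omega) > MAX_OMEGA_CONDITION:
        raise EstimationError("near-singular LD; prune or regularize")
    sol = np.linalg.solve(omega, np.column_stack([bx, by]))
    denom = float(bx @ sol[:, 0])
    beta = float(bx @ sol[:, 1]) / denom
    se_fixed = denom**-0.5
    resid = by - beta * bx
    q = float(resid @ np.linalg.solve(omega, resid))
    scale = 1.0
    q_p = None
    if h.k >= 2:
        q_p = float(stats.chi2.sf(q, h.k - 1))
        if effects_model == "multiplicative":
            scale = max(1.0, np.sqrt(q / (h.k - 1)))
    return _finalize(
        "ivw-correlated",
        beta,
        se_fixed * scale,
        h.k,
        q_statistic=q if h.k >= 2 else None,
        q_pvalue=q_p,
    )


def _oriented(h: HarmonizedDataset):
    sign = np.where(h.beta_exposure < 0, -1.0, 1.0)
    return sign * h.beta_exposure, sign * h.beta_outcome


def mr_egger(h: HarmonizedDataset) -> MREstimate:
    """MR-Egger regression: slope = causal effect, intercept = average
    directional pleiotropy, after orienting exposure effects nonnegative."""
    if h.k < 3:
        raise EstimationError("insufficient instruments for Egger (need k ≥ 3)")
    bx, by = _oriented(h)
    if np.ptp(bx) == 0:
        raise EstimationError("exposure effects all equal: collinear with intercept")
    w = 1.0 / h.se_outcome**2
    X = np.column_stack([np.ones_like(bx), bx])
    xtwx = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(xtwx, X.T @ (w * by))
    cov_fixed = np.linalg.inv(xtwx)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    scale = max(1.0, np.sqrt(q / (h.k - 2)))
    slope_se = float(np.sqrt(cov_fixed[1, 1])) * scale
    int_se = float(np.sqrt(cov_fixed[0, 0])) * scale
    z_int = coef[0] / int_se
    return _finalize(
        "egger",
        float(coef[1]),
        slope_se,
        h.k,
        q_statistic=q,
        q_pvalue=float(stats.chi2.sf(q, h.k - 2)),
        egger_intercept=float(coef[0]),
        intercept_se=int_se,
        p_intercept=float(2.0 * stats.norm.sf(abs(z_int))),
        i2gx=i2gx(h),
    )


def i2gx(h: HarmonizedDataset, variant: str = "weighted") -> float:
    """I²GX statistic for the NOME assumption of MR-Egger.

    Q_GX = Σ q_j (|bx_j| − b̄x)² with q_j = 1/se_xj² (``"weighted"``, the
    default) or the common value 1/mean(se_x²) (``"unweighted"``); I²GX =
    (Q_GX − (k−1))/Q_GX.  Raw value returned (may be negative); report
    floored at 0.  Values below 0.90 flag NOME violation.
    """
    if h.k < 2:
        raise EstimationError("I²GX needs k ≥ 2")
    bxa = np.abs(h.beta_exposure)
    if variant == "weighted":
        q = 1.0 / h.se_exposure**2
    elif variant == "unweighted":
        q = np.full(h.k, 1.0 / np.mean(h.se_exposure**2))
    else:
        raise ValueError(f"unknown I²GX variant: {variant!r}")
    bbar = float(np.sum(q * bxa) / np.sum(q))
    qgx = float(np.sum(q * (bxa - bbar) ** 2))
    if qgx == 0.0:
        return float("-inf")
    return (qgx - (h.k - 1)) / qgx


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r_sorted = r[order]
    wn = w[order] / np.sum(w)
    s = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, s, r_sorted))


def _weighted_median_rows(r: np.ndarray, w: np.ndarray) -> np.ndarray:
    # vectorized over rows (bootstrap replicates)
    order = np.argsort(r, axis=1)
    r_sorted = np.take_along_axis(r, order, axis=1)
    w_sorted = np.take_along_axis(w, order, axis=1)
    wn = w_sorted / np.sum(w_sorted, axis=1, keepdims=True)
    s = np.cumsum(wn, axis=1) - wn / 2.0
    out = np.empty(r.shape[0])
    for i in range(r.shape[0]):
        out[i] = np.interp(0.5, s[i], r_sorted[i])
    return out


def weighted_median(
    h: HarmonizedDataset, bootstrap_iters: int = 10_000, seed: int = 0
) -> MREstimate:
    """Weighted median of the Wald ratios (inverse-variance weights,
    first-order), with SE from a seeded parametric bootstrap.

    With ``bootstrap_iters=0`` the point estimate is returned with NaN SE
    and CI (useful in simulation loops where only the point matters).
    """
    if h.k < 3:
        raise EstimationError("weighted median needs k ≥ 3")
    bx, by = h.beta_exposure, h.beta_outcome
    _check_nonnull(bx)
    r = by / bx
    w = bx**2 / h.se_outcome**2
    point = _weighted_median_point(r, w)
    if bootstrap_iters == 0:
        return MREstimate(
            method="weighted-median",
            beta=point,
            se=float("nan"),
            ci_low=float("nan"),
            ci_high=float("nan"),
            pvalue=float("nan"),
            k=h.k,
        )
    rng = np.random.default_rng(seed)
    bx_b = rng.normal(bx, h.se_exposure, size=(bootstrap_iters, h.k))
    by_b = rng.normal(by, h.se_outcome, size=(bootstrap_iters, h.k))
    bx_b = np.where(bx_b == 0, np.finfo(float).tiny, bx_b)
    r_b = by_b / bx_b
    w_b = bx_b**2 / h.se_outcome**2
    boots = _weighted_median_rows(r_b, w_b)
    se = float(np.std(boots, ddof=1))
    return _finalize("weighted-median", point, se, h.k)


def cochran_q(h: HarmonizedDataset) -> tuple[float, int, float]:
    """Cochran's Q over the Wald ratios with IVW weights; p from χ²(k−1)."""
    if h.k < 2:
        raise EstimationError("Cochran's Q needs k ≥ 2")
    bx, by, sy = h.beta_exposure, h.beta_outcome, h.se_outcome
    _check_nonnull(bx)
    _, _, _, q, _ = _ivw_core(bx, by, sy)
    df = h.k - 1
    return q, df, float(stats.chi2.sf(q, df))
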