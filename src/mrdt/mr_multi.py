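"""Multivariable MR: joint direct effects of several exposures.

Regressing SNP-outcome effects jointly on the SNP effects for L exposures
(here typically L=2: LDL-c via a drug-target gene, and BMI) yields each
exposure's *direct* effect holding the others fixed.  Companion
diagnostics:

* conditional F — instrument strength for one exposure conditional on the
  others: the weighted residual heterogeneity of that exposure's SNP
  effects after regression on the other exposures' effects, divided by
  k − L.
* modified Q — heterogeneity statistic for horizontal pleiotropy that
  propagates uncertainty in the SNP-exposure effects into the weights:
  w_j = 1/(se_yj² + Σ_l θ_l² se_xlj²).

Cross-exposure GWAS sampling covariance is taken as zero by default
(separate samples); a supplied covariance enters the modified-Q weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .exceptions import EstimationError, ValidationError
from .instruments import InstrumentSet
from .mr_uni import Z95
from .sumstats import HarmonizedDataset, LDMatrix

__all__ = [
    "MVMRDataset",
    "MVMREstimate",
    "assemble_mvmr",
    "mvmr_ivw",
    "mvmr_egger",
    "conditional_f",
    "modified_q",
]


@dataclass
class MVMRDataset:
    """k SNPs × L exposures of betas/SEs plus the outcome associations."""

    rsids: tuple[str, ...]
    exposure_matrix: np.ndarray       # k × L
    exposure_se_matrix: np.ndarray    # k × L
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    exposure_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.rsids = tuple(self.rsids)
        self.exposure_matrix = np.atleast_2d(
            np.asarray(self.exposure_matrix, dtype=float)
        )
        self.exposure_se_matrix = np.atleast_2d(
            np.asarray(self.exposure_se_matrix, dtype=float)
        )
        self.beta_outcome = np.asarray(self.beta_outcome, dtype=float)
        self.se_outcome = np.asarray(self.se_outcome, dtype=float)
        if self.exposure_matrix.shape != self.exposure_se_matrix.shape:
            raise ValidationError("exposure beta and SE matrices differ in shape")
        if self.exposure_matrix.shape[0] != len(self.rsids):
            raise ValidationError("exposure matrix rows do not match rsids")
        if not self.exposure_labels:
            self.exposure_labels = tuple(
                f"exposure{l + 1}" for l in range(self.L)
            )
        if self.k <= self.L:
            raise ValidationError(f"need more SNPs than exposures (k={self.k}, L={self.L})")
        if np.any(np.all(self.exposure_matrix == 0, axis=1)):
            raise ValidationError("all-zero exposure row")

    @property
    def k(self) -> int:
        return len(self.rsids)

    @property
    def L(self) -> int:
        return self.exposure_matrix.shape[1]

    @classmethod
    def from_harmonized(
        cls, h: HarmonizedDataset, exposure_labels: Sequence[str] = ()
    ) -> "MVMRDataset":
        if h.beta_exposure2 is None:
            raise ValidationError("harmonized dataset has no second exposure")
        return cls(
            rsids=h.rsids,
            exposure_matrix=np.column_stack([h.beta_exposure, h.beta_exposure2]),
            exposure_se_matrix=np.column_stack([h.se_exposure, h.se_exposure2]),
            beta_outcome=h.beta_outcome,
            se_outcome=h.se_outcome,
            exposure_labels=tuple(exposure_labels),
        )

    def permuted(self, order: Sequence[int]) -> "MVMRDataset":
        order = list(order)
        return MVMRDataset(
            rsids=tuple(self.rsids[i] for i in order),
            exposure_matrix=self.exposure_matrix[order],
            exposure_se_matrix=self.exposure_se_matrix[order],
            beta_outcome=self.beta_outcome[order],
            se_outcome=self.se_outcome[order],
            exposure_labels=self.exposure_labels,
        )


@dataclass
class MVMREstimate:
    """Per-exposure direct effects with MVMR diagnostics."""

    method: str
    beta: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pvalue: np.ndarray
    k: int
    exposure_labels: tuple[str, ...] = ()
    egger_intercept: float | None = None
    intercept_se: float | None = None
    p_intercept: float | None = None
    conditional_f: np.ndarray | None = None
    q_modified: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    selected: bool = False

    def odds_ratios(self) -> np.ndarray:
        """(L, 3) array of OR, ci_low, ci_high by exponentiation."""
        return np.exp(np.column_stack([self.beta, self.ci_low, self.ci_high]))


def assemble_mvmr(
    primary_set: InstrumentSet,
    secondary_set: InstrumentSet,
    h: HarmonizedDataset,
    ld: LDMatrix | None = None,
    ld_guard_r2: float = 0.001,
    exposure_labels: Sequence[str] = (),
) -> tuple[MVMRDataset, list[str]]:
    """Union the two instrument sets over a two-exposure harmonized dataset.

    Secondary-exposure SNPs correlated (r² ≥ ``ld_guard_r2``) with any
    primary-set SNP are removed and logged; pairs absent from ``ld`` are
    assumed uncorrelated (different genomic regions).
    """
    log: list[str] = []
    primary = [r for r in primary_set.rsids if r in h.rsids]
    secondary = []
    for rsid in secondary_set.rsids:
        if rsid not in h.rsids or rsid in primary:
            continue
        clash = None
        if ld is not None:
            idx = set(ld.rsids)
            for p in primary:
                if rsid in idx and p in idx and ld.r2(rsid, p) >= ld_guard_r2:
                    clash = (p, ld.r2(rsid, p))
                    break
        if clash:
            log.append(
                f"excluded {rsid}: r²={clash[1]:.3g} ≥ {ld_guard_r2} with {clash[0]}"
            )
        else:
            secondary.append(rsid)
    rsids = primary + secondary
    sub = h.restrict(rsids)
    d = MVMRDataset.from_harmonized(sub, exposure_labels=exposure_labels)
    return d, log


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray):
    xtwx = X.T @ (w[:, None] * X)
    # rank check on the column-normalized matrix: scale differences between
    # exposures are fine, true collinearity is not
    norms = np.sqrt(np.diag(xtwx))
    if np.any(norms == 0) or np.linalg.cond(xtwx / np.outer(norms, norms)) > 1e8:
        raise EstimationError("collinear exposures")
    coef = np.linalg.solve(xtwx, X.T @ (w * y))
    cov_fixed = np.linalg.inv(xtwx)
    q = float(np.sum(w * (y - X @ coef) ** 2))
    return coef, cov_fixed, q


def _finalize_mv(method, coef, cov, scale, d, slope_idx, **extra) -> MVMREstimate:
    beta = coef[slope_idx]
    se = np.sqrt(np.diag(cov))[slope_idx] * scale
    z = beta / se
    return MVMREstimate(
        method=method,
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        pvalue=2.0 * stats.norm.sf(np.abs(z)),
        k=d.k,
        exposure_labels=d.exposure_labels,
        conditional_f=np.array([conditional_f(d, l) for l in range(d.L)]),
        **extra,
    )


def mvmr_ivw(d: MVMRDataset) -> MVMREstimate:
    """MVMR-IVW: weighted multivariable regression of the SNP-outcome
    effects on the SNP-exposure matrix, no intercept, weights 1/se_y²;
    SEs scaled by max(1, sqrt(Q_res/(k−L)))."""
    w = 1.0 / d.se_outcome**2
    coef, cov, q = _wls(d.exposure_matrix, d.beta_outcome, w)
    scale = max(1.0, np.sqrt(q / (d.k - d.L)))
    est = _finalize_mv("mvmr-ivw", coef, cov, scale, d, slice(None))
    qa, qdf, qp = modified_q(d, coef)
    est.q_modified, est.q_df, est.q_pvalue = qa, qdf, qp
    return est


def mvmr_egger(d: MVMRDataset, orient_on: int = 0) -> MVMREstimate:
    """MVMR-Egger: rows sign-oriented so exposure ``orient_on`` has
    nonnegative betas, then weighted regression with an intercept whose
    two-sided p is reported as P_intercept."""
    if d.k < d.L + 2:
        raise EstimationError(
            f"MVMR-Egger needs k ≥ L+2 (k={d.k}, L={d.L})"
        )
    sign = np.where(d.exposure_matrix[:, orient_on] < 0, -1.0, 1.0)
    X = sign[:, None] * d.exposure_matrix
    y = sign * d.beta_outcome
    w = 1.0 / d.se_outcome**2
    Xi = np.column_stack([np.ones(d.k), X])
    coef, cov, q = _wls(Xi, y, w)
    scale = max(1.0, np.sqrt(q / (d.k - d.L - 1)))
    int_se = float(np.sqrt(cov[0, 0])) * scale
    est = _finalize_mv(
        "mvmr-egger",
        coef,
        cov,
        scale,
        d,
        slice(1, None),
        egger_intercept=float(coef[0]),
        intercept_se=int_se,
        p_intercept=float(2.0 * stats.norm.sf(abs(coef[0] / int_se))),
    )
    return est


def conditional_f(d: MVMRDataset, l: int, cross_cov: float = 0.0) -> float:
    """Conditional instrument strength of exposure ``l`` given the others.

    Weighted (1/se_xl²) regression without intercept of exposure l's SNP
    effects on the other exposures'; F_cond = Q_xl/(k−L) with Q_xl the
    weighted residual sum of squares.  ``cross_cov`` is accepted for a
    nonzero cross-exposure sampling covariance (subtracted from the
    residual quadratic form); the default 0 reflects separate samples.
    """
    x = d.exposure_matrix[:, l]
    se = d.exposure_se_matrix[:, l]
    others = np.delete(d.exposure_matrix, l, axis=1)
    w = 1.0 / se**2
    if others.shape[1] == 0:
        resid = x
    else:
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(sw[:, None] * others, sw * x, rcond=None)
        resid = x - others @ coef
    q = float(np.sum(w * resid**2)) - cross_cov
    return max(q, 0.0) / (d.k - d.L)


def modified_q(
    d: MVMRDataset, theta: Sequence[float]
) -> tuple[float, int, float]:
    """Modified Q statistic for horizontal pleiotropy in MVMR.

    Q_A = Σ_j w_j (by_j − Σ_l θ_l x_lj)² with weights propagating the
    SNP-exposure uncertainty, w_j = 1/(se_yj² + Σ_l θ_l² se_xlj²);
    df = k − L, p from χ².
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (d.L,):
        raise ValidationError(f"theta must have length L={d.L}")
    var = d.se_outcome**2 + (d.exposure_se_matrix**2) @ (theta**2)
    resid = d.beta_outcome - d.exposure_matrix @ theta
    q = float(np.sum(resid**2 / var))
    df = d.k - d.L
    return q, df, float(stats.chi2.sf(q, df))
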