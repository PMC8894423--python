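"""Synthetic two-sample GWAS summary statistics with known truth.

Every estimator in this package, and the full study workflow, can be
exercised without downloading any real GWAS by generating summary tables
under the same linear model the estimators assume:

    bx_j  =  γ_j + N(0, se_xj)                (observed SNP-exposure effect)
    by_j  =  θ·γ_j + α_j + N(0, se_yj)        (observed SNP-outcome effect)

with per-SNP standard errors derived from GWAS sample sizes via the
standard approximation se ≈ 1/sqrt(2·n·eaf·(1−eaf)) for a unit-variance
trait, and pleiotropy α_j drawn under one of four regimes: ``none``,
``balanced`` (mean-zero), ``directional`` (mean μ, the InSiDE-compatible
violation MR-Egger targets), or ``inside`` (α correlated with instrument
strength, violating InSiDE).

LD-correlated blocks draw the sampling errors of exposure and outcome
effects jointly with the requested within-block correlation, and emit
that generating matrix as the :class:`~mrdt.sumstats.LDMatrix` the
correlated-IVW estimator consumes.  Allele codings include configurable
fractions of palindromic SNPs and of strand-flipped/swapped entries in
the outcome table so harmonization is exercised end to end.

A single seed drives independent per-table substreams, so regenerating
with the same seed reproduces files byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from types import SimpleNamespace

import numpy as np
from scipy import stats

from .exceptions import ValidationError
from .sumstats import AssociationTable, LDMatrix
import pandas as pd

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_univariable",
    "simulate_ld_block",
    "simulate_mvmr",
    "simulate_effect_arrays",
    "simulate_mvmr_arrays",
]

_NONPAL = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PAL = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

PLEIOTROPY_REGIMES = ("none", "balanced", "directional", "inside")


@dataclass
class SimulationConfig:
    """Generating parameters for a synthetic two-sample MR study.

    ``theta`` holds the true causal effect(s); its length sets the number
    of exposures L.  ``gamma_range`` bounds the uniform draw of true
    instrument effects.  Sample sizes map to SEs for unit-variance traits.
    """

    seed: int
    k: int = 50
    theta: tuple[float, ...] = (0.5,)
    gamma_range: tuple[float, float] = (0.1, 0.3)
    pleiotropy: str = "none"
    mu: float = 0.0          # mean pleiotropic effect (directional)
    tau: float = 0.0         # pleiotropy SD (balanced/directional/inside)
    inside_slope: float = 0.3  # dα/dγ under the InSiDE-violating regime
    invalid_fraction: float = 1.0  # fraction of SNPs carrying pleiotropy
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    eaf_range: tuple[float, float] = (0.1, 0.9)
    ld_block_sizes: tuple[int, ...] | None = None
    block_r: float = 0.0
    palindromic_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    swap_fraction: float = 0.3
    # multivariable extras: split of SNPs between the two instrument
    # groups and the group-1 cross-effect on exposure 2 (statin→BMI analogue)
    k_split: tuple[int, int] | None = None
    cross_effect: float = 0.33
    rsid_offset: int = 1

    def validate(self) -> None:
        if self.k <= len(self.theta):
            raise ValidationError("need k > L")
        if self.pleiotropy not in PLEIOTROPY_REGIMES:
            raise ValidationError(f"unknown pleiotropy regime: {self.pleiotropy!r}")
        if self.tau < 0 or self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValidationError("tau and sample sizes must be positive")
        if self.ld_block_sizes is not None:
            if sum(self.ld_block_sizes) != self.k:
                raise ValidationError("LD block sizes must sum to k")
            if abs(self.block_r) >= 1:
                raise ValidationError("within-block |r| must be < 1")
        for frac in (self.palindromic_fraction, self.strand_flip_fraction,
                     self.swap_fraction, self.invalid_fraction):
            if not 0 <= frac <= 1:
                raise ValidationError("fractions must lie in [0,1]")


@dataclass
class SimulationTruth:
    """Generating parameters paired with the emitted tables."""

    seed: int
    theta: tuple[float, ...]
    pleiotropy: str
    gamma: list        # true instrument effects (per exposure for MVMR)
    alpha: list        # true pleiotropic effects
    config: dict
    paths: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(c) for c in np.random.SeedSequence(seed).spawn(n)]


def _se_from_n(n: int, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    k = len(gamma)
    if cfg.pleiotropy == "none":
        return np.zeros(k)
    if cfg.pleiotropy == "balanced":
        alpha = rng.normal(0.0, cfg.tau, k)
    elif cfg.pleiotropy == "directional":
        alpha = cfg.mu + rng.normal(0.0, cfg.tau, k)
    else:  # inside: pleiotropy tracks instrument strength
        centered = gamma - np.mean(gamma)
        alpha = cfg.mu + cfg.inside_slope * centered + rng.normal(0.0, cfg.tau, k)
    # only the first invalid_fraction of SNPs are pleiotropic ("invalid")
    n_invalid = int(round(cfg.invalid_fraction * k))
    alpha[n_invalid:] = 0.0
    return alpha


def _block_correlation(cfg: SimulationConfig) -> np.ndarray:
    rho = np.eye(cfg.k)
    if cfg.ld_block_sizes is None:
        return rho
    start = 0
    for size in cfg.ld_block_sizes:
        block = np.full((size, size), cfg.block_r)
        np.fill_diagonal(block, 1.0)
        rho[start:start + size, start:start + size] = block
        start += size
    return rho


def _correlated_noise(rho_chol: np.ndarray, se: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    return se * (rho_chol @ rng.standard_normal(len(se)))


def simulate_effect_arrays(cfg: SimulationConfig) -> SimpleNamespace:
    """Core numeric draw (no tables): gamma, observed bx/by, SEs, alpha, eaf.

    Used directly in simulation loops where constructing full allele-coded
    tables would be wasted work.
    """
    cfg.validate()
    rng_g, rng_eaf, rng_x, rng_y, rng_a = _streams(cfg.seed, 5)
    theta = cfg.theta[0]
    gamma = rng_g.uniform(*cfg.gamma_range, cfg.k)
    eaf = rng_eaf.uniform(*cfg.eaf_range, cfg.k)
    se_x = _se_from_n(cfg.n_exposure, eaf)
    se_y = _se_from_n(cfg.n_outcome, eaf)
    alpha = _draw_alpha(cfg, gamma, rng_a)
    rho = _block_correlation(cfg)
    if cfg.ld_block_sizes is None:
        ex = rng_x.standard_normal(cfg.k) * se_x
        ey = rng_y.standard_normal(cfg.k) * se_y
    else:
        chol = np.linalg.cholesky(rho)
        ex = _correlated_noise(chol, se_x, rng_x)
        ey = _correlated_noise(chol, se_y, rng_y)
    bx = gamma + ex
    by = theta * gamma + alpha + ey
    return SimpleNamespace(
        gamma=gamma, alpha=alpha, eaf=eaf,
        bx=bx, se_x=se_x, by=by, se_y=se_y, rho=rho,
    )


def _assign_alleles(k: int, pal_fraction: float, rng: np.random.Generator):
    n_pal = int(round(pal_fraction * k))
    pal_mask = np.zeros(k, dtype=bool)
    pal_mask[rng.choice(k, n_pal, replace=False)] = True
    ea, oa = [], []
    for j in range(k):
        pool = _PAL if pal_mask[j] else _NONPAL
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)
    return np.array(ea), np.array(oa), pal_mask


def _table(rsids, ea, oa, beta, se, eaf, n, trait, sex="overall") -> AssociationTable:
    z = beta / se
    df = pd.DataFrame({
        "rsid": rsids,
        "effect_allele": ea,
        "other_allele": oa,
        "beta": beta,
        "se": se,
        "pvalue": 2.0 * stats.norm.sf(np.abs(z)),
        "eaf": eaf,
        "n": float(n),
    })
    return AssociationTable(trait=trait, sex=sex, df=df)


def _recode_outcome(ea, oa, beta, eaf, flip_frac, swap_frac,
                    rng: np.random.Generator):
    """Strand-flip and allele-swap a fraction of outcome rows (consistently
    with the underlying effect) to exercise harmonization."""
    k = len(ea)
    ea, oa = ea.copy(), oa.copy()
    beta, eaf = beta.copy(), eaf.copy()
    flip = rng.random(k) < flip_frac
    swap = rng.random(k) < swap_frac
    for j in range(k):
        if flip[j] and _COMPLEMENT[ea[j]] != oa[j]:  # skip palindromic: flip = swap
            ea[j], oa[j] = _COMPLEMENT[ea[j]], _COMPLEMENT[oa[j]]
        if swap[j]:
            ea[j], oa[j] = oa[j], ea[j]
            beta[j] = -beta[j]
            eaf[j] = 1.0 - eaf[j]
    return ea, oa, beta, eaf


def simulate_univariable(
    cfg: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, SimulationTruth]:
    """Emit exposure and outcome tables under the univariable model."""
    arrays = simulate_effect_arrays(cfg)
    # spawn children are indexed, so streams 0-4 match those used inside
    # simulate_effect_arrays; 5 and 6 are fresh
    rng_alleles, rng_recode = _streams(cfg.seed, 7)[5:]
    k = cfg.k
    rsids = [f"rs{cfg.rsid_offset + j}" for j in range(k)]
    ea, oa, _ = _assign_alleles(k, cfg.palindromic_fraction, rng_alleles)
    exposure = _table(rsids, ea, oa, arrays.bx, arrays.se_x, arrays.eaf,
                      cfg.n_exposure, trait="exposure")
    ea_o, oa_o, by_o, eaf_o = _recode_outcome(
        ea, oa, arrays.by, arrays.eaf,
        cfg.strand_flip_fraction, cfg.swap_fraction, rng_recode,
    )
    outcome = _table(rsids, ea_o, oa_o, by_o, arrays.se_y, eaf_o,
                     cfg.n_outcome, trait="outcome")
    truth = SimulationTruth(
        seed=cfg.seed,
        theta=tuple(cfg.theta),
        pleiotropy=cfg.pleiotropy,
        gamma=arrays.gamma.tolist(),
        alpha=arrays.alpha.tolist(),
        config=dataclasses.asdict(cfg),
    )
    return exposure, outcome, truth


def simulate_ld_block(
    cfg: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, LDMatrix, SimulationTruth]:
    """Univariable simulation with LD-correlated blocks; the emitted
    LDMatrix equals the generating correlation."""
    if cfg.ld_block_sizes is None:
        raise ValidationError("simulate_ld_block requires ld_block_sizes")
    exposure, outcome, truth = simulate_univariable(cfg)
    rho = _block_correlation(cfg)
    ld = LDMatrix(tuple(exposure.rsids), rho)
    return exposure, outcome, ld, truth


def simulate_mvmr_arrays(cfg: SimulationConfig) -> SimpleNamespace:
    """Core numeric draw for the two-exposure design (no tables)."""
    cfg.validate()
    if len(cfg.theta) != 2:
        raise ValidationError("simulate_mvmr needs theta of length 2")
    k1, k2 = cfg.k_split if cfg.k_split else (cfg.k // 2, cfg.k - cfg.k // 2)
    if k1 + k2 != cfg.k:
        raise ValidationError("k_split must sum to k")
    rng_g, rng_eaf, rng_x1, rng_x2, rng_y, rng_a = _streams(cfg.seed, 6)
    k = cfg.k
    gamma = rng_g.uniform(*cfg.gamma_range, k)
    # true per-SNP effects on each exposure
    g1 = np.where(np.arange(k) < k1, gamma, 0.0)
    g2 = np.where(np.arange(k) < k1, cfg.cross_effect * gamma, gamma)
    eaf = rng_eaf.uniform(*cfg.eaf_range, k)
    se_x1 = _se_from_n(cfg.n_exposure, eaf)
    se_x2 = _se_from_n(cfg.n_exposure, eaf)
    se_y = _se_from_n(cfg.n_outcome, eaf)
    alpha = _draw_alpha(cfg, gamma, rng_a)
    bx1 = g1 + rng_x1.standard_normal(k) * se_x1
    bx2 = g2 + rng_x2.standard_normal(k) * se_x2
    by = cfg.theta[0] * g1 + cfg.theta[1] * g2 + alpha + rng_y.standard_normal(k) * se_y
    return SimpleNamespace(
        g1=g1, g2=g2, alpha=alpha, eaf=eaf,
        bx1=bx1, se_x1=se_x1, bx2=bx2, se_x2=se_x2, by=by, se_y=se_y,
    )


def simulate_mvmr(
    cfg: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, AssociationTable, SimulationTruth]:
    """Two-exposure simulation: group 1 drives exposure 1 (with a
    configurable cross-effect on exposure 2, the statin→BMI analogue),
    group 2 drives exposure 2 only; the outcome combines both direct
    effects plus pleiotropy."""
    a = simulate_mvmr_arrays(cfg)
    rng_alleles, rng_recode = _streams(cfg.seed, 8)[6:]
    k = cfg.k
    g1, g2, alpha, eaf = a.g1, a.g2, a.alpha, a.eaf
    bx1, se_x1, bx2, se_x2 = a.bx1, a.se_x1, a.bx2, a.se_x2
    by, se_y = a.by, a.se_y
    rsids = [f"rs{cfg.rsid_offset + j}" for j in range(k)]
    ea, oa, _ = _assign_alleles(k, cfg.palindromic_fraction, rng_alleles)
    exp1 = _table(rsids, ea, oa, bx1, se_x1, eaf, cfg.n_exposure, trait="exposure1")
    exp2 = _table(rsids, ea, oa, bx2, se_x2, eaf, cfg.n_exposure, trait="exposure2")
    ea_o, oa_o, by_o, eaf_o = _recode_outcome(
        ea, oa, by, eaf, cfg.strand_flip_fraction, cfg.swap_fraction, rng_recode
    )
    outcome = _table(rsids, ea_o, oa_o, by_o, se_y, eaf_o, cfg.n_outcome,
                     trait="outcome")
    truth = SimulationTruth(
        seed=cfg.seed,
        theta=tuple(cfg.theta),
        pleiotropy=cfg.pleiotropy,
        gamma=[g1.tolist(), g2.tolist()],
        alpha=alpha.tolist(),
        config=dataclasses.asdict(cfg),
    )
    return exp1, exp2, outcome, truth
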