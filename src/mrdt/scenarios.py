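"""Ready-made synthetic study scenarios.

:func:`paper_like_study` emulates the statistical structure of a
drug-target MR study of lipid modifiers: three mimicked drugs (statins
via a correlated HMGCR block, PCSK9 inhibitors via independent PCSK9
variants, ezetimibe via an NPC1L1 variant available only through its
proxy), a polygenic BMI instrument set, and LDL-c / BMI / IHD summary
tables for all of them.  Generating truth:

* statins raise BMI by 0.33 SD per SD *decrease* in LDL-c; the other two
  drugs have no BMI effect (their screens should halt);
* BMI raises IHD log-odds by 0.45 per SD (OR ≈ 1.57);
* the direct LDL→IHD effect is 0.6 per SD increase (OR ≈ 0.55 per unit
  decrease).

GWAS sample sizes (344k LDL-c, 700k BMI, 361k IHD) mirror the order of
magnitude of the large biobank/consortium studies such analyses draw on.
One BMI variant is generated in LD with the statin lead SNP so the
multivariable LD guard has something to remove, and a fraction of
outcome-table rows are allele-swapped to exercise harmonization.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .sumstats import AssociationTable, LDMatrix
from .synthetic import (
    SimulationTruth,
    _assign_alleles,
    _recode_outcome,
    _se_from_n,
    _streams,
    _table,
)
from .workflow import StudyConfig, Thresholds, UnitScaling

__all__ = ["paper_like_study", "TRUE_EFFECTS"]

#: generating causal structure of the paper-like scenario
TRUE_EFFECTS = {
    "statin_bmi_per_ldl_decrease": 0.33,
    "bmi_ihd_logodds": 0.45,
    "ldl_ihd_logodds": 0.6,
}

_N_LDL = 344_000
_N_BMI = 700_000
_N_IHD = 361_000


def paper_like_study(
    seed: int,
    n_bmi_snps: int = 50,
    inject_pleiotropy: bool = False,
    pleiotropy_mu: float = 0.02,
    bootstrap_iters: int = 1000,
) -> tuple[StudyConfig, SimulationTruth]:
    """Build a fully in-memory synthetic study configuration.

    With ``inject_pleiotropy`` the BMI instruments acquire a directional
    pleiotropic effect on IHD of mean ``pleiotropy_mu`` (log-odds), which
    should fire the multivariable Egger-fallback rule.
    """
    from .instruments import default_registry

    registry = default_registry()
    statin_rsids = registry["statins"]["rsids"]
    pcsk9_rsids = registry["PCSK9 inhibitors"]["rsids"]
    eze_available = ["rs10260606", "rs217386", "rs7791240", "rs10234070",
                     "rs2300414"]  # lead rs2073547 absent; proxy available
    bmi_rsids = ["rs2119753"] + [f"rs90{j:05d}" for j in range(1, n_bmi_snps)]
    rsids = statin_rsids + pcsk9_rsids + eze_available + bmi_rsids
    k = len(rsids)
    idx = {r: i for i, r in enumerate(rsids)}

    (rng_g, rng_eaf, rng_x, rng_b, rng_y, rng_a,
     rng_alleles, rng_rec_b, rng_rec_y) = _streams(seed, 9)

    # true marginal LDL effects per effect allele
    gamma_ldl = np.zeros(k)
    n_statin, n_pcsk9 = len(statin_rsids), len(pcsk9_rsids)
    gamma_ldl[:n_statin] = rng_g.uniform(0.10, 0.20, n_statin)
    gamma_ldl[n_statin:n_statin + n_pcsk9] = rng_g.uniform(0.08, 0.15, n_pcsk9)
    eze_lo = n_statin + n_pcsk9
    gamma_ldl[eze_lo] = 0.15  # proxy of the lead NPC1L1 variant
    gamma_ldl[eze_lo + 1:eze_lo + 5] = rng_g.uniform(0.05, 0.10, 4)

    # true BMI effects: statins act through LDL lowering (+0.33 SD per SD
    # decrease → −0.33·γ per LDL-raising allele); polygenic BMI variants
    gamma_bmi = np.zeros(k)
    gamma_bmi[:n_statin] = (
        -TRUE_EFFECTS["statin_bmi_per_ldl_decrease"] * gamma_ldl[:n_statin]
    )
    bmi_lo = eze_lo + 5
    gamma_bmi[bmi_lo:] = rng_g.uniform(0.03, 0.08, k - bmi_lo)

    # IHD log-odds: direct LDL effect plus BMI effect, plus optional
    # directional pleiotropy on the BMI instruments
    alpha = np.zeros(k)
    if inject_pleiotropy:
        alpha[bmi_lo:] = pleiotropy_mu + rng_a.normal(0, pleiotropy_mu / 4, k - bmi_lo)
    gamma_ihd = (
        TRUE_EFFECTS["ldl_ihd_logodds"] * gamma_ldl
        + TRUE_EFFECTS["bmi_ihd_logodds"] * gamma_bmi
        + alpha
    )

    # LD: statin block at r=0.5; one BMI variant in LD with the statin lead
    rho = np.eye(k)
    block = np.full((n_statin, n_statin), 0.5)
    np.fill_diagonal(block, 1.0)
    rho[:n_statin, :n_statin] = block
    j_guard = idx["rs2119753"]
    j_lead = idx["rs12916"]
    rho[j_guard, j_lead] = rho[j_lead, j_guard] = 0.20
    for j in range(n_statin):
        if j != j_lead:
            rho[j_guard, j] = rho[j, j_guard] = 0.10
    assert np.linalg.eigvalsh(rho).min() > 0

    eaf = rng_eaf.uniform(0.1, 0.9, k)
    se_ldl = _se_from_n(_N_LDL, eaf)
    se_bmi = _se_from_n(_N_BMI, eaf)
    se_ihd = _se_from_n(_N_IHD, eaf)
    chol = np.linalg.cholesky(rho)
    bx_ldl = gamma_ldl + se_ldl * (chol @ rng_x.standard_normal(k))
    bx_bmi = gamma_bmi + se_bmi * (chol @ rng_b.standard_normal(k))
    by_ihd = gamma_ihd + se_ihd * (chol @ rng_y.standard_normal(k))

    ea, oa, _ = _assign_alleles(k, 0.0, rng_alleles)
    ldl_table = _table(rsids, ea, oa, bx_ldl, se_ldl, eaf, _N_LDL, trait="LDL")
    ea_b, oa_b, bx_bmi_c, eaf_b = _recode_outcome(
        ea, oa, bx_bmi, eaf, 0.2, 0.3, rng_rec_b
    )
    bmi_table = _table(rsids, ea_b, oa_b, bx_bmi_c, se_bmi, eaf_b, _N_BMI,
                       trait="BMI")
    ea_y, oa_y, by_ihd_c, eaf_y = _recode_outcome(
        ea, oa, by_ihd, eaf, 0.2, 0.3, rng_rec_y
    )
    ihd_table = _table(rsids, ea_y, oa_y, by_ihd_c, se_ihd, eaf_y, _N_IHD,
                       trait="IHD")

    statin_ld = LDMatrix(tuple(statin_rsids), rho[:n_statin, :n_statin])
    guard_cols = statin_rsids + bmi_rsids
    guard_sel = [idx[r] for r in guard_cols]
    guard_ld = LDMatrix(tuple(guard_cols), rho[np.ix_(guard_sel, guard_sel)])

    config = StudyConfig(
        tables={
            ("LDL", "overall"): ldl_table,
            ("BMI", "overall"): bmi_table,
            ("IHD", "overall"): ihd_table,
        },
        ld={"statins": statin_ld, "mvmr_guard": guard_ld},
        registry=registry,
        bmi_instruments=list(bmi_rsids),
        thresholds=Thresholds(),
        scaling=UnitScaling(),
        bootstrap_iters=bootstrap_iters,
        seed=seed,
    )
    truth = SimulationTruth(
        seed=seed,
        theta=(TRUE_EFFECTS["ldl_ihd_logodds"], TRUE_EFFECTS["bmi_ihd_logodds"]),
        pleiotropy="directional" if inject_pleiotropy else "none",
        gamma=[gamma_ldl.tolist(), gamma_bmi.tolist()],
        alpha=alpha.tolist(),
        config={
            "scenario": "paper_like",
            "seed": seed,
            "n_bmi_snps": n_bmi_snps,
            "inject_pleiotropy": inject_pleiotropy,
            "pleiotropy_mu": pleiotropy_mu,
            "true_effects": dict(TRUE_EFFECTS),
            "n": {"LDL": _N_LDL, "BMI": _N_BMI, "IHD": _N_IHD},
        },
    )
    return config, truth
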