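"""The study's end-to-end decision procedure and reporting.

The analysis mirrors a drug-target MR study of lipid-lowering therapies:

1. *Screen* each genetically mimicked drug (statins/HMGCR, PCSK9
   inhibitors, ezetimibe/NPC1L1) for an effect on BMI; only drugs whose
   95% CI excludes zero proceed to further analysis.
2. *Univariable* MR of the drug-instrumented LDL-c effect, and of BMI, on
   ischemic heart disease (IHD), with IVW as the primary estimator and
   MR-Egger (with the I²GX/NOME flag) and the weighted median as
   sensitivity analyses; correlated within-gene instrument sets are
   analysed by GLS-IVW with their LD matrix.
3. *Multivariable* MR of the drug and BMI jointly on IHD, with
   conditional F statistics for instrument strength and the modified Q
   statistic for horizontal pleiotropy; the MR-Egger estimate is reported
   when either the modified Q or the Egger intercept is significant.

Drug estimates are reported per unit *decrease* in LDL-c (mimicking
treatment), as odds ratios for the binary outcome.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import ValidationError
from .instruments import (
    InstrumentSet,
    ProxyMap,
    default_registry,
    load_registry,
    save_registry,
    substitute_proxies,
)
from .mr_multi import MVMREstimate, assemble_mvmr, mvmr_egger, mvmr_ivw
from .mr_uni import MREstimate, ivw, ivw_correlated, mr_egger, weighted_median
from .sumstats import (
    AssociationTable,
    LDMatrix,
    harmonize,
    read_association_table,
    read_ld_matrix,
    write_association_table,
    write_ld_matrix,
)

__all__ = [
    "UnitScaling",
    "Thresholds",
    "StudyConfig",
    "ResultRow",
    "convert_units",
    "ci_excludes_zero",
    "select_estimator",
    "screen_drug_on_bmi",
    "run_univariable",
    "run_multivariable",
    "render_tables",
]


@dataclass
class UnitScaling:
    """Population SDs used to convert SD-scale MR estimates to natural units."""

    sd_ldl: float = 0.871   # mmol/L per SD of LDL-c
    sd_bmi: float = 4.77    # kg/m² per SD of BMI
    height_m: float = 1.70  # metres

    def __post_init__(self) -> None:
        if min(self.sd_ldl, self.sd_bmi, self.height_m) <= 0:
            raise ValidationError("unit scalings must be positive")


def convert_units(
    beta_sd_per_sd: float, scaling: UnitScaling | None = None
) -> tuple[float, float]:
    """Convert an SD-per-SD statin→BMI effect to natural units.

    Returns (kg/m² of BMI, kg of weight) per 1 mmol/L lower LDL-c:
    bmi = beta · sd_bmi / sd_ldl and weight = bmi · height².  Values are
    unrounded; presentation rounds to 2 and 1 decimals respectively.
    """
    scaling = scaling or UnitScaling()
    bmi = beta_sd_per_sd * scaling.sd_bmi / scaling.sd_ldl
    weight = bmi * scaling.height_m**2
    return bmi, weight


@dataclass
class Thresholds:
    alpha: float = 0.05
    p_instrument: float = 5e-8
    r2_independent: float = 0.05
    r2_guard: float = 0.001
    i2gx_floor: float = 0.90

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.p_instrument < 1):
            raise ValidationError("alpha and p_instrument must lie in (0,1)")
        if not (0 <= self.r2_guard <= self.r2_independent <= 1):
            raise ValidationError("r² thresholds out of range")


@dataclass
class StudyConfig:
    """Everything one study run needs: tables per trait×sex, LD matrices,
    the instrument registry, thresholds, unit scalings and seeds."""

    tables: dict[tuple[str, str], AssociationTable] = field(default_factory=dict)
    ld: dict[str, LDMatrix] = field(default_factory=dict)
    registry: dict = field(default_factory=default_registry)
    bmi_instruments: list[str] = field(default_factory=list)
    exposure_trait: str = "LDL"
    mediator_trait: str = "BMI"
    outcome_trait: str = "IHD"
    thresholds: Thresholds = field(default_factory=Thresholds)
    scaling: UnitScaling = field(default_factory=UnitScaling)
    bootstrap_iters: int = 2000
    seed: int = 0
    orientation: str = "decrease"  # report drug effects per unit decrease in LDL-c

    def table(self, trait: str, sex: str) -> AssociationTable:
        try:
            return self.tables[(trait, sex)]
        except KeyError:
            raise KeyError(f"no table for trait={trait!r}, sex={sex!r}") from None

    # -- persistence -------------------------------------------------------

    def save(self, outdir: str | Path) -> Path:
        """Write tables, LD matrices, registry and a cfg.yaml under outdir."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        doc: dict = {"tables": {}, "ld": {}}
        for (trait, sex), table in self.tables.items():
            rel = f"{trait}_{sex}.tsv"
            write_association_table(table, outdir / rel)
            doc["tables"].setdefault(trait, {})[sex] = rel
        for label, ld in self.ld.items():
            rel = f"ld_{label.replace(' ', '_')}.tsv"
            write_ld_matrix(ld, outdir / rel)
            doc["ld"][label] = rel
        save_registry(self.registry, outdir / "registry.yaml")
        doc.update(
            registry="registry.yaml",
            bmi_instruments=list(self.bmi_instruments),
            exposure_trait=self.exposure_trait,
            mediator_trait=self.mediator_trait,
            outcome_trait=self.outcome_trait,
            thresholds=dataclasses.asdict(self.thresholds),
            scaling=dataclasses.asdict(self.scaling),
            bootstrap_iters=self.bootstrap_iters,
            seed=self.seed,
            orientation=self.orientation,
        )
        cfg_path = outdir / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(doc, sort_keys=False))
        return cfg_path

    @classmethod
    def load(cls, cfg_path: str | Path) -> "StudyConfig":
        cfg_path = Path(cfg_path)
        base = cfg_path.parent
        doc = yaml.safe_load(cfg_path.read_text())
        tables = {}
        for trait, by_sex in doc.get("tables", {}).items():
            for sex, rel in by_sex.items():
                tables[(trait, sex)] = read_association_table(
                    base / rel, trait=trait, sex=sex
                )
        ld = {
            label: read_ld_matrix(base / rel)
            for label, rel in doc.get("ld", {}).items()
        }
        reg = doc.get("registry", "default")
        registry = default_registry() if reg == "default" else load_registry(base / reg)
        return cls(
            tables=tables,
            ld=ld,
            registry=registry,
            bmi_instruments=list(doc.get("bmi_instruments", [])),
            exposure_trait=doc.get("exposure_trait", "LDL"),
            mediator_trait=doc.get("mediator_trait", "BMI"),
            outcome_trait=doc.get("outcome_trait", "IHD"),
            thresholds=Thresholds(**doc.get("thresholds", {})),
            scaling=UnitScaling(**doc.get("scaling", {})),
            bootstrap_iters=int(doc.get("bootstrap_iters", 2000)),
            seed=int(doc.get("seed", 0)),
            orientation=doc.get("orientation", "decrease"),
        )


@dataclass
class ResultRow:
    """One line of a paper-style result table."""

    exposure: str
    sex: str
    n_snp: int
    method: str
    estimate: float       # OR if or_scale else beta
    ci_low: float
    ci_high: float
    p: float
    p_intercept: float | None = None
    or_scale: bool = True
    notes: str = ""


def _registry_proxies(entry: dict) -> ProxyMap:
    mapping = {k: (v[0], float(v[1])) for k, v in entry.get("proxies", {}).items()}
    return ProxyMap(mapping=mapping)


def _drug_dataset(
    drug: str,
    outcome_trait: str,
    sex: str,
    config: StudyConfig,
    which: str = "lead",
):
    """Harmonized dataset restricted to the drug's resolved instruments."""
    ldl = config.table(config.exposure_trait, sex)
    out = config.table(outcome_trait, sex)
    entry = config.registry[drug]
    requested = entry["lead"] if which == "lead" else entry["rsids"]
    available = set(ldl.rsids) & set(out.rsids)
    resolved, log = substitute_proxies(requested, available, _registry_proxies(entry))
    h = harmonize(ldl, out)
    return h.restrict(resolved), resolved, log


def _orient_for_report(est: MREstimate, config: StudyConfig) -> MREstimate:
    return est.oriented(-1) if config.orientation == "decrease" else est


def ci_excludes_zero(ci_low: float, ci_high: float) -> bool:
    """Strict exclusion: a CI exactly touching 0 does not count."""
    return bool(ci_low > 0 or ci_high < 0)


def select_estimator(
    q_pvalue: float | None, p_intercept: float | None, alpha: float = 0.05
) -> tuple[str, list[str]]:
    """Egger-fallback rule: report MVMR-Egger when either the modified Q
    or the Egger intercept is significant, else MVMR-IVW.  Returns the
    selected method and the list of triggers."""
    triggers = []
    if q_pvalue is not None and q_pvalue < alpha:
        triggers.append(f"modified Q significant (p={q_pvalue:.3g})")
    if p_intercept is not None and p_intercept < alpha:
        triggers.append(f"Egger intercept significant (p={p_intercept:.3g})")
    return ("MVMR-Egger" if triggers else "MVMR-IVW"), triggers


def screen_drug_on_bmi(
    drug: str, config: StudyConfig, sex: str = "overall"
) -> tuple[MREstimate, bool]:
    """Univariable IVW of the drug-instrumented LDL effect on BMI.

    Proceed iff the 95% CI strictly excludes zero ("lack of association"
    halts further analysis of that drug).
    """
    h, _, _ = _drug_dataset(drug, config.mediator_trait, sex, config, which="lead")
    est = ivw(h)
    proceed = ci_excludes_zero(est.ci_low, est.ci_high)
    return _orient_for_report(est, config), proceed


def _row_from_estimate(
    exposure: str,
    sex: str,
    est: MREstimate,
    method: str,
    or_scale: bool,
    notes: str = "",
) -> ResultRow:
    if or_scale:
        e, lo, hi = est.odds_ratio()
    else:
        e, lo, hi = est.beta, est.ci_low, est.ci_high
    return ResultRow(
        exposure=exposure,
        sex=sex,
        n_snp=est.k,
        method=method,
        estimate=e,
        ci_low=lo,
        ci_high=hi,
        p=est.pvalue,
        p_intercept=est.p_intercept,
        or_scale=or_scale,
        notes=notes,
    )


def run_univariable(
    exposure: str, sex: str, config: StudyConfig, or_scale: bool = True
) -> list[ResultRow]:
    """Univariable MR of one exposure on IHD, paper-table style.

    Drug exposures get the independent lead-set IVW plus, when an LD
    matrix is registered for the drug, the correlated-set GLS-IVW.  BMI
    gets IVW, MR-Egger (flagged when I²GX is below the NOME floor) and
    the weighted median.
    """
    rows: list[ResultRow] = []
    if exposure in config.registry:
        h, _, _ = _drug_dataset(
            exposure, config.outcome_trait, sex, config, which="lead"
        )
        est = _orient_for_report(ivw(h), config)
        rows.append(_row_from_estimate(exposure, sex, est, "IVW", or_scale))
        if exposure in config.ld:
            hc, resolved, _ = _drug_dataset(
                exposure, config.outcome_trait, sex, config, which="all"
            )
            ld = config.ld[exposure]
            estc = _orient_for_report(ivw_correlated(hc, ld), config)
            rows.append(
                _row_from_estimate(exposure, sex, estc, "IVW-correlated", or_scale)
            )
        return rows
    if exposure != config.mediator_trait:
        raise KeyError(f"unknown exposure: {exposure!r}")
    bmi = config.table(config.mediator_trait, sex)
    ihd = config.table(config.outcome_trait, sex)
    h = harmonize(bmi, ihd)
    keep = [r for r in config.bmi_instruments if r in h.rsids]
    h = h.restrict(keep)
    rows.append(_row_from_estimate(exposure, sex, ivw(h), "IVW", or_scale))
    egger = mr_egger(h)
    note = ""
    if egger.i2gx is not None and egger.i2gx < config.thresholds.i2gx_floor:
        note = (
            f"NOME violated (<{config.thresholds.i2gx_floor:.2f}): "
            f"I²GX={max(egger.i2gx, 0.0):.3f}"
        )
    rows.append(_row_from_estimate(exposure, sex, egger, "MR-Egger", or_scale, note))
    wm = weighted_median(
        h, bootstrap_iters=config.bootstrap_iters, seed=config.seed
    )
    rows.append(_row_from_estimate(exposure, sex, wm, "weighted-median", or_scale))
    return rows


def run_multivariable(
    config: StudyConfig,
    sex: str = "overall",
    drug: str = "statins",
    which: str = "lead",
    or_scale: bool = True,
    orient_on: int = 1,
) -> tuple[list[ResultRow], MVMREstimate, MVMREstimate, dict]:
    """MVMR of the drug and BMI jointly on IHD with the selection rule.

    Computes MVMR-IVW and MVMR-Egger, conditional F per exposure and the
    modified Q (plug-in IVW coefficients); the reported method is Egger
    when the modified Q p or the Egger intercept p falls below alpha,
    otherwise IVW.  The decision and its trigger go in the notes.

    Egger rows are oriented on the polygenic exposure (index 1, BMI) by
    default: every BMI instrument has a well-measured nonzero BMI effect,
    so orientation is effectively deterministic, whereas orienting on the
    drug column would flip the many near-null drug entries by their
    sampling noise and bias the intercept.
    """
    ldl = config.table(config.exposure_trait, sex)
    ihd = config.table(config.outcome_trait, sex)
    bmi = config.table(config.mediator_trait, sex)
    h = harmonize(ldl, ihd, more=[bmi])
    entry = config.registry[drug]
    requested = entry["lead"] if which == "lead" else entry["rsids"]
    resolved, log = substitute_proxies(
        requested, set(h.rsids), _registry_proxies(entry)
    )
    drug_set = InstrumentSet(label=drug, rsids=tuple(resolved), mode="independent")
    bmi_set = InstrumentSet(
        label=config.mediator_trait,
        rsids=tuple(r for r in config.bmi_instruments if r in h.rsids),
        mode="independent",
    )
    d, guard_log = assemble_mvmr(
        drug_set,
        bmi_set,
        h,
        ld=config.ld.get("mvmr_guard"),
        ld_guard_r2=config.thresholds.r2_guard,
        exposure_labels=(drug, config.mediator_trait),
    )
    ivw_est = mvmr_ivw(d)
    egger_est = mvmr_egger(d, orient_on=orient_on)
    selected, triggers = select_estimator(
        ivw_est.q_pvalue, egger_est.p_intercept, config.thresholds.alpha
    )
    ivw_est.selected = selected == "MVMR-IVW"
    egger_est.selected = selected == "MVMR-Egger"
    note = (
        f"Egger selected: {'; '.join(triggers)}" if triggers else "IVW selected"
    )
    info = {
        "selected": selected,
        "triggers": triggers,
        "conditional_f": dict(zip(d.exposure_labels, ivw_est.conditional_f)),
        "q_modified": ivw_est.q_modified,
        "q_df": ivw_est.q_df,
        "q_pvalue": ivw_est.q_pvalue,
        "guard_log": guard_log,
        "proxy_log": log,
        "k_drug": len([r for r in resolved if r in d.rsids]),
        "k": d.k,
    }
    rows: list[ResultRow] = []
    decrease = config.orientation == "decrease"
    k_drug = info["k_drug"]
    n_per_exposure = (k_drug, d.k - k_drug)
    for est, method in ((ivw_est, "MVMR-IVW"), (egger_est, "MVMR-Egger")):
        for l, label in enumerate(d.exposure_labels):
            sign = -1.0 if (decrease and l == 0) else 1.0
            beta = sign * est.beta[l]
            lo, hi = sorted((sign * est.ci_low[l], sign * est.ci_high[l]))
            if or_scale:
                e, lo, hi = float(np.exp(beta)), float(np.exp(lo)), float(np.exp(hi))
            else:
                e = float(beta)
            rows.append(
                ResultRow(
                    exposure=label,
                    sex=sex,
                    n_snp=n_per_exposure[l],
                    method=method,
                    estimate=e,
                    ci_low=lo,
                    ci_high=hi,
                    p=float(est.pvalue[l]),
                    p_intercept=est.p_intercept,
                    or_scale=or_scale,
                    notes=note if method == selected else "",
                )
            )
    return rows, ivw_est, egger_est, info


# -- presentation ---------------------------------------------------------

_COLUMNS = (
    "exposure", "sex", "n_snp", "method",
    "estimate", "ci", "p", "p_intercept", "notes",
)


def _fmt_p(p: float | None) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return ""
    return f"{p:.2e}" if p < 1e-3 else f"{p:.3f}"


def _render_rows(rows: list[ResultRow]) -> list[dict]:
    ordered = sorted(
        enumerate(rows), key=lambda t: (t[1].exposure, t[1].sex, t[1].method, t[0])
    )
    out = []
    for _, r in ordered:
        out.append({
            "exposure": r.exposure,
            "sex": r.sex,
            "n_snp": str(r.n_snp),
            "method": r.method,
            "estimate": f"{r.estimate:.2f}",
            "ci": f"{r.ci_low:.2f} to {r.ci_high:.2f}",
            "p": _fmt_p(r.p),
            "p_intercept": _fmt_p(r.p_intercept),
            "notes": r.notes,
        })
    return out


def render_tables(rows: list[ResultRow]) -> tuple[str, str]:
    """Render result rows as a TSV string and a GitHub-markdown table.

    Deterministic order (exposure, sex, method; input order breaks ties);
    estimates and CIs to 2 decimals, p in scientific notation below 1e-3.
    """
    if not rows:
        raise ValidationError("no rows to render")
    rendered = _render_rows(rows)
    tsv_lines = ["\t".join(_COLUMNS)]
    tsv_lines += ["\t".join(r[c] for c in _COLUMNS) for r in rendered]
    md_lines = [
        "| " + " | ".join(_COLUMNS) + " |",
        "| " + " | ".join("---" for _ in _COLUMNS) + " |",
    ]
    md_lines += ["| " + " | ".join(r[c] for c in _COLUMNS) + " |" for r in rendered]
    return "\n".join(tsv_lines) + "\n", "\n".join(md_lines) + "\n"
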