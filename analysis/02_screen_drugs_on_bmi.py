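#!/usr/bin/env python
"""Screen each genetically mimicked lipid modifier for an effect on BMI.

Univariable IVW of the drug-instrumented LDL-c effect on BMI, reported
per unit *decrease* in LDL-c; a drug proceeds to the IHD analyses only
when its 95% CI excludes zero.  The statin effect is also converted to
natural units (kg/m² and kg per 1 mmol/L lower LDL-c) using UK-Biobank
scale SDs.
"""

import argparse
from pathlib import Path

from mrdt.workflow import StudyConfig, convert_units, screen_drug_on_bmi


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", type=Path, default=Path("results/sim/clean/cfg.yaml"))
    ap.add_argument("--out", type=Path, default=Path("results/tables"))
    args = ap.parse_args()

    config = StudyConfig.load(args.config)
    args.out.mkdir(parents=True, exist_ok=True)
    lines = ["drug\tbeta_per_ldl_decrease\tci_low\tci_high\tproceed"]
    for drug in config.registry:
        est, proceed = screen_drug_on_bmi(drug, config)
        lines.append(f"{drug}\t{est.beta:.4f}\t{est.ci_low:.4f}"
                     f"\t{est.ci_high:.4f}\t{proceed}")
        verdict = "proceeds to IHD analysis" if proceed else "halts (no BMI effect)"
        print(f"{drug}: {est.beta:.3f} SD BMI per SD lower LDL-c "
              f"[{est.ci_low:.3f}, {est.ci_high:.3f}] -> {verdict}")
        if drug == "statins" and proceed:
            bmi, weight = convert_units(est.beta, config.scaling)
            print(f"  in natural units: +{bmi:.2f} kg/m² BMI and +{weight:.1f} kg "
                  "weight per 1 mmol/L lower LDL-c")
    (args.out / "screen_bmi.tsv").write_text("\n".join(lines) + "\n")
    print(f"wrote {args.out / 'screen_bmi.tsv'}")


if __name__ == "__main__":
    main()
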