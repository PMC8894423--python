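"""Instrument selection for drug-target and polygenic exposures.

Drug-target MR restricts instruments to variants in or near the gene
encoding the drug's target, so the genetic effect mimics pharmacological
modulation: HMGCR for statins, PCSK9 for PCSK9 inhibitors, NPC1L1 for
ezetimibe.  This module carries the registry of those variant sets,
strength filtering (the approximate F statistic beta²/se²), greedy
p-ranked LD pruning to an independent set, and proxy substitution for
variants missing from a particular GWAS.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .exceptions import EstimationError, ValidationError
from .sumstats import AssociationTable, LDMatrix, SummaryAssociation

__all__ = [
    "InstrumentSet",
    "ProxyMap",
    "DEFAULT_REGISTRY",
    "f_statistic",
    "summarize_strength",
    "prune_independent",
    "substitute_proxies",
    "load_registry",
    "save_registry",
]

#: Drug-target variant registry: label -> gene, full correlated set, the
#: independent subset used in primary analyses, and proxy substitutions.
DEFAULT_REGISTRY: dict[str, dict] = {
    "statins": {
        "gene": "HMGCR",
        "rsids": ["rs12916", "rs10066707", "rs17238484", "rs2006760",
                  "rs2303152", "rs5909"],
        "lead": ["rs12916"],
        "proxies": {},
    },
    "PCSK9 inhibitors": {
        "gene": "PCSK9",
        "rsids": ["rs11206510", "rs2149041", "rs7552841", "rs2479409",
                  "rs2479394", "rs10888897", "rs562556"],
        "lead": ["rs11206510", "rs2149041", "rs7552841"],
        "proxies": {},
    },
    "ezetimibe": {
        "gene": "NPC1L1",
        "rsids": ["rs2073547", "rs217386", "rs7791240", "rs10234070",
                  "rs2300414"],
        "lead": ["rs2073547"],
        "proxies": {"rs2073547": ["rs10260606", 0.99]},
    },
}


def load_registry(path: str | Path) -> dict[str, dict]:
    with open(path) as fh:
        reg = yaml.safe_load(fh)
    for label, entry in reg.items():
        entry.setdefault("proxies", {})
        entry.setdefault("lead", entry["rsids"][:1])
    return reg


def save_registry(registry: Mapping[str, dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(registry), fh, sort_keys=False)


def default_registry() -> dict[str, dict]:
    return copy.deepcopy(DEFAULT_REGISTRY)


@dataclass
class InstrumentSet:
    """An ordered instrument list with its selection provenance."""

    label: str
    rsids: tuple[str, ...]
    mode: str = "independent"  # independent | correlated
    ld: LDMatrix | None = None
    selection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rsids = tuple(self.rsids)
        if self.mode not in ("independent", "correlated"):
            raise ValidationError(f"unknown instrument mode: {self.mode!r}")
        if self.mode == "correlated":
            if self.ld is None:
                raise ValidationError("correlated instrument set requires an LD matrix")
            if set(self.ld.rsids) != set(self.rsids):
                raise ValidationError("LD matrix must cover exactly the instrument rsids")

    @property
    def k(self) -> int:
        return len(self.rsids)


@dataclass
class ProxyMap:
    """requested rsid -> (proxy rsid, r²), all r² above ``min_r2``."""

    mapping: dict[str, tuple[str, float]] = field(default_factory=dict)
    min_r2: float = 0.8

    def __post_init__(self) -> None:
        for req, (proxy, r2) in self.mapping.items():
            if r2 < self.min_r2:
                raise ValidationError(
                    f"proxy {proxy} for {req} has r²={r2} below minimum {self.min_r2}"
                )

    @classmethod
    def from_tsv(cls, path: str | Path, min_r2: float = 0.8) -> "ProxyMap":
        df = pd.read_csv(path, sep="\t")
        mapping = {
            str(row["requested"]): (str(row["proxy"]), float(row["r2"]))
            for _, row in df.iterrows()
        }
        return cls(mapping=mapping, min_r2=min_r2)


def f_statistic(assoc: SummaryAssociation | float, se: float | None = None) -> float:
    """Approximate per-SNP instrument F statistic, (beta/se)².

    Accepts either a :class:`SummaryAssociation` or ``(beta, se)`` floats.
    """
    if isinstance(assoc, SummaryAssociation):
        beta, se = assoc.beta, assoc.se
    else:
        beta = float(assoc)
    if se is None or se <= 0:
        raise ValidationError("F statistic requires se > 0")
    return (beta / se) ** 2


def summarize_strength(table: AssociationTable) -> pd.DataFrame:
    """Per-SNP F statistics with summary attributes.

    The returned frame has columns ``rsid, F``; ``.attrs`` carries
    ``median_f`` and ``n_strong`` (count of SNPs with F > 10).
    """
    if not len(table):
        raise ValidationError("cannot summarize an empty table")
    beta = table.df["beta"].to_numpy(dtype=float)
    se = table.df["se"].to_numpy(dtype=float)
    f = (beta / se) ** 2
    out = pd.DataFrame({"rsid": table.rsids, "F": f})
    out.attrs["median_f"] = float(np.median(f))
    out.attrs["n_strong"] = int(np.sum(f > 10))
    return out


def _pvalue_for(assoc: SummaryAssociation) -> float:
    if assoc.pvalue is not None:
        return assoc.pvalue
    return float(2.0 * stats.norm.sf(abs(assoc.beta / assoc.se)))


def prune_independent(
    candidates: Sequence[str],
    exposure: AssociationTable,
    ld: LDMatrix,
    r2_max: float = 0.05,
    p_max: float = 5e-8,
    label: str = "",
) -> InstrumentSet:
    """Greedy clumping-style selection of an independent instrument set.

    Candidates with exposure p above ``p_max`` are dropped; survivors are
    ranked by ascending p (ties: larger |beta|, then rsid) and selected
    greedily, removing everything with r² ≥ ``r2_max`` against each pick.
    The returned order is the selection order.
    """
    survivors = []
    for rsid in candidates:
        a = exposure.get(rsid)
        p = _pvalue_for(a)
        if p <= p_max:
            survivors.append((p, -abs(a.beta), rsid))
    if not survivors:
        raise EstimationError("no instruments pass thresholds")
    survivors.sort()
    queue = [rsid for _, _, rsid in survivors]
    selected: list[str] = []
    while queue:
        top = queue.pop(0)
        selected.append(top)
        queue = [r for r in queue if ld.r2(top, r) < r2_max]
    return InstrumentSet(
        label=label or exposure.trait,
        rsids=tuple(selected),
        mode="independent",
        ld=None,
        selection_params={"r2_max": r2_max, "p_max": p_max},
    )


def substitute_proxies(
    requested: Sequence[str],
    available: set[str] | Sequence[str],
    proxies: ProxyMap | None = None,
) -> tuple[list[str], list[str]]:
    """Resolve each requested rsid against an available set, substituting
    registered proxies for missing variants.

    Returns the resolved list and a log of substitutions/exclusions.
    """
    available = set(available)
    proxies = proxies or ProxyMap()
    resolved: list[str] = []
    log: list[str] = []
    for rsid in requested:
        if rsid in available:
            resolved.append(rsid)
            continue
        entry = proxies.mapping.get(rsid)
        if entry is not None and entry[0] in available:
            proxy, r2 = entry
            resolved.append(proxy)
            log.append(f"{rsid} unavailable; substituted proxy {proxy} (r²={r2})")
        else:
            log.append(f"{rsid} unavailable; no proxy found, dropped")
    return resolved, log
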