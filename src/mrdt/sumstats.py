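"""GWAS summary-association tables, LD matrices and allele harmonization.

Two-sample Mendelian randomization works entirely from per-SNP summary
statistics: for every variant we need its effect size (beta), standard
error and allele coding in the exposure GWAS and in the outcome GWAS.
Before any estimator can run, the two tables must be *harmonized* — every
retained SNP expressed on the same effect allele in both studies, with
strand flips resolved and palindromic (A/T, C/G) variants handled by an
explicit policy.

File dialect: tab-separated text with a header, '.' decimal point.
Required columns ``rsid, effect_allele, other_allele, beta, se``; optional
``pvalue, eaf, n``.  LD matrices are square tab-separated tables whose
first row and first column carry the rsIDs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, HarmonizationError, ValidationError

__all__ = [
    "SummaryAssociation",
    "AssociationTable",
    "LDMatrix",
    "HarmonizedDataset",
    "is_palindromic",
    "read_association_table",
    "write_association_table",
    "read_ld_matrix",
    "write_ld_matrix",
    "harmonize",
]

_BASES = ("A", "C", "G", "T")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_COLUMNS = ("pvalue", "eaf", "n")

#: float format guaranteeing exact text round-trips of IEEE doubles
FLOAT_FORMAT = "%.17g"


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T or C/G pairs cannot be strand-resolved from alleles alone."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP's association with one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float | None = None
    eaf: float | None = None
    n: float | None = None

    def problems(self) -> list[str]:
        """Return the invariant violations of this row (empty if valid)."""
        out: list[str] = []
        if self.effect_allele not in _BASES or self.other_allele not in _BASES:
            out.append("allele not one of A/C/G/T")
        elif self.effect_allele == self.other_allele:
            out.append("identical alleles")
        if not np.isfinite(self.beta):
            out.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append("nonpositive SE")
        if self.pvalue is not None and not (0.0 <= self.pvalue <= 1.0):
            out.append("p-value outside [0,1]")
        if self.eaf is not None and not (0.0 < self.eaf < 1.0):
            out.append("EAF outside (0,1)")
        return out

    @property
    def palindromic(self) -> bool:
        return is_palindromic(self.effect_allele, self.other_allele)


@dataclass
class AssociationTable:
    """Per-trait collection of :class:`SummaryAssociation`, unique by rsid.

    ``rejected`` maps rsids of rows dropped during validation to the reason.
    """

    trait: str
    sex: str = "overall"
    df: pd.DataFrame = field(default_factory=pd.DataFrame)
    rejected: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.df.empty and not len(self.df.columns):
            self.df = pd.DataFrame(
                columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
            )
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {', '.join(missing)}")
        for c in OPTIONAL_COLUMNS:
            if c not in self.df.columns:
                self.df[c] = np.nan
        dup = self.df["rsid"][self.df["rsid"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate rsid(s): {', '.join(sorted(set(dup)))}")
        self.df = self.df.reset_index(drop=True)

    @classmethod
    def from_associations(
        cls,
        associations: Iterable[SummaryAssociation],
        trait: str,
        sex: str = "overall",
    ) -> "AssociationTable":
        rows = [vars(a) for a in associations]
        df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS))
        return cls(trait=trait, sex=sex, df=df)

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rsid: str) -> bool:
        return rsid in set(self.df["rsid"])

    def get(self, rsid: str) -> SummaryAssociation:
        sub = self.df[self.df["rsid"] == rsid]
        if not len(sub):
            raise KeyError(rsid)
        row = sub.iloc[0]
        return SummaryAssociation(
            rsid=row["rsid"],
            effect_allele=row["effect_allele"],
            other_allele=row["other_allele"],
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=None if pd.isna(row["pvalue"]) else float(row["pvalue"]),
            eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
            n=None if pd.isna(row["n"]) else float(row["n"]),
        )

    def __iter__(self) -> Iterator[SummaryAssociation]:
        for rsid in self.rsids:
            yield self.get(rsid)

    def subset(self, rsids: Sequence[str]) -> "AssociationTable":
        """Rows for ``rsids`` in the given order; missing rsids raise KeyError."""
        have = set(self.df["rsid"])
        missing = [r for r in rsids if r not in have]
        if missing:
            raise KeyError(f"rsid(s) not in table: {', '.join(missing)}")
        df = self.df.set_index("rsid").loc[list(rsids)].reset_index()
        return AssociationTable(trait=self.trait, sex=self.sex, df=df)


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    keep: list[int] = []
    rejected: dict[str, str] = {}
    for i, row in df.iterrows():
        assoc = SummaryAssociation(
            rsid=str(row["rsid"]),
            effect_allele=str(row["effect_allele"]).upper(),
            other_allele=str(row["other_allele"]).upper(),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pvalue=None if pd.isna(row.get("pvalue")) else float(row["pvalue"]),
            eaf=None if pd.isna(row.get("eaf")) else float(row["eaf"]),
        )
        probs = assoc.problems()
        if probs:
            rejected[assoc.rsid] = "; ".join(probs)
        else:
            keep.append(i)
    return df.loc[keep], rejected


def read_association_table(
    path: str | Path, trait: str, sex: str = "overall"
) -> AssociationTable:
    """Read a TSV summary-statistics table; invalid rows are dropped with
    reasons recorded in ``table.rejected``; duplicate rsids are an error."""
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for c in OPTIONAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()
    for c in ("beta", "se", "pvalue", "eaf", "n"):
        df[c] = df[c].astype(float)
    clean, rejected = _validate_rows(df)
    table = AssociationTable(trait=trait, sex=sex, df=clean.reset_index(drop=True))
    table.rejected = rejected
    return table


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    table.df[cols].to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


@dataclass
class LDMatrix:
    """Signed LD correlation matrix over an ordered rsid set."""

    rsids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.rsids = tuple(self.rsids)
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.rsids)
        if self.r.shape != (k, k):
            raise FormatError(
                f"LD matrix shape {self.r.shape} does not match {k} rsids"
            )
        if np.max(np.abs(self.r - self.r.T)) > 1e-8:
            raise ValidationError("LD matrix asymmetric beyond 1e-8")
        self.r = (self.r + self.r.T) / 2.0
        if np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-8:
            raise ValidationError("LD matrix diagonal is not 1")
        np.fill_diagonal(self.r, 1.0)
        if np.max(np.abs(self.r)) > 1.0 + 1e-12:
            raise ValidationError("LD correlation outside [-1,1]")
        if np.linalg.eigvalsh(self.r).min() < -1e-6:
            raise ValidationError("LD matrix not positive semi-definite")

    @property
    def index(self) -> dict[str, int]:
        return {r: i for i, r in enumerate(self.rsids)}

    def submatrix(self, rsids: Sequence[str]) -> "LDMatrix":
        idx = self.index
        missing = [r for r in rsids if r not in idx]
        if missing:
            raise KeyError(f"rsid(s) not in LD matrix: {', '.join(missing)}")
        sel = [idx[r] for r in rsids]
        return LDMatrix(tuple(rsids), self.r[np.ix_(sel, sel)])

    def r2(self, a: str, b: str) -> float:
        idx = self.index
        return float(self.r[idx[a], idx[b]] ** 2)


def read_ld_matrix(path: str | Path) -> LDMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"{path}: LD matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: row and column rsids differ")
    return LDMatrix(tuple(str(r) for r in df.index), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=list(ld.rsids), columns=list(ld.rsids)).to_csv(
        path, sep="\t", float_format=FLOAT_FORMAT
    )


@dataclass
class HarmonizedDataset:
    """Per-SNP exposure and outcome effects aligned on a shared effect allele.

    ``beta_exposure2`` / ``se_exposure2`` carry a second exposure (e.g. BMI)
    for multivariable runs.  ``excluded`` maps dropped rsids to the reason.
    """

    rsids: tuple[str, ...]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    beta_exposure2: np.ndarray | None = None
    se_exposure2: np.ndarray | None = None
    excluded: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rsids = tuple(self.rsids)
        for name in ("beta_exposure", "se_exposure", "beta_outcome", "se_outcome"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.beta_exposure2 is not None:
            self.beta_exposure2 = np.asarray(self.beta_exposure2, dtype=float)
            self.se_exposure2 = np.asarray(self.se_exposure2, dtype=float)

    @property
    def k(self) -> int:
        return len(self.rsids)

    def restrict(self, rsids: Sequence[str]) -> "HarmonizedDataset":
        """Subset (and reorder) to ``rsids``; missing rsids raise KeyError."""
        idx = {r: i for i, r in enumerate(self.rsids)}
        missing = [r for r in rsids if r not in idx]
        if missing:
            raise KeyError(f"rsid(s) not harmonized: {', '.join(missing)}")
        sel = [idx[r] for r in rsids]
        return HarmonizedDataset(
            rsids=tuple(rsids),
            beta_exposure=self.beta_exposure[sel],
            se_exposure=self.se_exposure[sel],
            beta_outcome=self.beta_outcome[sel],
            se_outcome=self.se_outcome[sel],
            beta_exposure2=None
            if self.beta_exposure2 is None
            else self.beta_exposure2[sel],
            se_exposure2=None
            if self.se_exposure2 is None
            else self.se_exposure2[sel],
            excluded=dict(self.excluded),
        )

    def single(self, rsid: str) -> "HarmonizedDataset":
        return self.restrict([rsid])


def _align_one(
    ref_ea: str,
    ref_oa: str,
    assoc: SummaryAssociation,
) -> tuple[float, float | None] | str:
    """Align ``assoc`` onto the reference allele pair.

    Returns ``(sign, aligned_eaf)`` or an exclusion-reason string.  Strand
    flips (both alleles complemented) are treated as equivalent codings
    before swap detection.
    """
    ea, oa = assoc.effect_allele, assoc.other_allele
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    if (ea, oa) == (ref_ea, ref_oa) or (cea, coa) == (ref_ea, ref_oa):
        return 1.0, assoc.eaf
    if (oa, ea) == (ref_ea, ref_oa) or (coa, cea) == (ref_ea, ref_oa):
        return -1.0, None if assoc.eaf is None else 1.0 - assoc.eaf
    return "allele mismatch"


def _palindromic_ok(
    eaf_ref: float | None, eaf_other: float | None, window: tuple[float, float]
) -> bool:
    if eaf_ref is None or eaf_other is None:
        return False
    lo, hi = window
    if lo <= eaf_ref <= hi or lo <= eaf_other <= hi:
        return False
    return (eaf_ref - 0.5) * (eaf_other - 0.5) > 0


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    more: Sequence[AssociationTable] = (),
    palindromic_policy: str = "exclude",
    eaf_window: tuple[float, float] = (0.42, 0.58),
) -> HarmonizedDataset:
    """Align outcome (and any further tables) on the exposure's effect allele.

    Swapped allele orders negate the aligned beta; non-resolvable allele
    sets are excluded as "allele mismatch".  Palindromic SNPs are excluded
    under the default policy, or retained under ``"infer"`` when both EAFs
    fall on the same side of 0.5 and outside ``eaf_window``.
    """
    if palindromic_policy not in ("exclude", "infer"):
        raise ValueError(f"unknown palindromic policy: {palindromic_policy!r}")
    tables = [outcome, *more]
    if len(more) > 1:
        raise NotImplementedError("at most one extra exposure table is supported")
    shared = [r for r in exposure.rsids if all(r in t for t in tables)]
    if not shared:
        raise HarmonizationError("no shared instruments")

    kept: list[str] = []
    excluded: dict[str, str] = {}
    bx, sx, by, sy = [], [], [], []
    bx2, sx2 = [], []
    for rsid in shared:
        e = exposure.get(rsid)
        if e.palindromic:
            if palindromic_policy == "exclude":
                excluded[rsid] = "palindromic"
                continue
            # infer mode: nominal alignment below, guarded by the EAF rule
        aligned: list[tuple[float, SummaryAssociation]] = []
        reason = None
        for t in tables:
            a = t.get(rsid)
            res = _align_one(e.effect_allele, e.other_allele, a)
            if isinstance(res, str):
                reason = res
                break
            sign, eaf_aligned = res
            if e.palindromic and not _palindromic_ok(e.eaf, eaf_aligned, eaf_window):
                reason = "palindromic, ambiguous or missing EAF"
                break
            aligned.append((sign, a))
        if reason is not None:
            excluded[rsid] = reason
            continue
        kept.append(rsid)
        bx.append(e.beta)
        sx.append(e.se)
        sign, a = aligned[0]
        by.append(sign * a.beta)
        sy.append(a.se)
        if more:
            sign2, a2 = aligned[1]
            bx2.append(sign2 * a2.beta)
            sx2.append(a2.se)
    if not kept:
        raise HarmonizationError(
            "no shared instruments survived harmonization: "
            + "; ".join(f"{r}: {v}" for r, v in excluded.items())
        )
    return HarmonizedDataset(
        rsids=tuple(kept),
        beta_exposure=np.array(bx),
        se_exposure=np.array(sx),
        beta_outcome=np.array(by),
        se_outcome=np.array(sy),
        beta_exposure2=np.array(bx2) if more else None,
        se_exposure2=np.array(sx2) if more else None,
        excluded=excluded,
    )
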