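"""Core domain types for stratified case-control SNP analysis.

All downstream statistics consume these containers; file parsing lives in
:mod:`apmstrata.io` and never leaks into the statistical modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class Stratum(str, Enum):
    """Smoking stratum used throughout the study design."""

    SMOKERS = "smokers"
    NEVER_SMOKERS = "never_smokers"


class CaseStatus(str, Enum):
    CASE = "case"
    CONTROL = "control"


#: Ordinal ordering of chemotherapy response, worst to best.
RESPONSE_LEVELS = ("progressive", "stable", "partial", "complete")

#: Clinical columns recognised in cohort tables (beyond id/status/stratum).
CLINICAL_COLUMNS = (
    "sex",
    "age_at_diagnosis",
    "pack_years",
    "stage",
    "ecog",
    "surgery",
    "response",
    "survival_time",
    "event",
)


@dataclass(frozen=True)
class SnpDef:
    """Identity of a biallelic SNP.

    Parameters
    ----------
    snp_id : str
        rsID, e.g. ``"rs26653"``.
    gene : str
        Gene symbol the SNP belongs to.
    alleles : tuple of str
        ``(major, minor)`` allele characters; the minor allele defines the
        dosage coding (0/1/2 copies of the minor allele).
    """

    snp_id: str
    gene: str
    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        major, minor = self.alleles
        if major == minor:
            raise ValueError(f"{self.snp_id}: alleles must be distinct")

    @property
    def major(self) -> str:
        return self.alleles[0]

    @property
    def minor(self) -> str:
        return self.alleles[1]

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        """``(major-hom, het, minor-hom)`` labels, e.g. ``("GG","GC","CC")``."""
        major, minor = self.alleles
        return (major * 2, major + minor, minor * 2)

    def dosage_label(self, dosage: int) -> str:
        """Genotype label for a minor-allele dosage in {0,1,2}."""
        return self.genotype_labels[dosage]


@dataclass(frozen=True)
class StratifiedGenotypeCounts:
    """2 (case/control) x 3 (genotype) count table for one SNP and stratum.

    Counts are ordered ``(minor-hom, het, major-hom)`` as printed in the
    source genotype tables.
    """

    snp: SnpDef
    stratum: Stratum
    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for name, triple in (("case", self.case_counts), ("control", self.control_counts)):
            if len(triple) != 3 or any(c < 0 for c in triple):
                raise ValueError(f"{self.snp.snp_id}: {name} counts must be 3 non-negative ints")
            if sum(triple) <= 0:
                raise ValueError(f"{self.snp.snp_id}: {name} total must be positive")

    def counts(self, status: CaseStatus) -> tuple[int, int, int]:
        return self.case_counts if status is CaseStatus.CASE else self.control_counts

    def n_cases(self) -> int:
        return sum(self.case_counts)

    def n_controls(self) -> int:
        return sum(self.control_counts)

    def dosage_counts(self, status: CaseStatus) -> np.ndarray:
        """Counts reordered to dosage order (0, 1, 2 minor alleles)."""
        mh, het, Mh = self.counts(status)
        return np.array([Mh, het, mh], dtype=float)


class CohortTable:
    """Individual-level genotype + clinical table.

    Thin wrapper over a :class:`pandas.DataFrame` with mandatory columns
    ``id``, ``status`` (case/control), ``stratum`` (smokers/never_smokers)
    and one column per SNP holding minor-allele dosages in {0, 1, 2} with
    ``NaN`` for missing. Clinical covariates are optional columns.
    """

    REQUIRED = ("id", "status", "stratum")

    def __init__(self, df: pd.DataFrame, snp_ids: Sequence[str]):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"cohort table missing required columns: {missing}")
        absent = [s for s in snp_ids if s not in df.columns]
        if absent:
            raise ValueError(f"cohort table missing SNP columns: {absent}")
        df = df.reset_index(drop=True).copy()
        bad_status = set(df["status"].unique()) - {s.value for s in CaseStatus}
        if bad_status:
            raise ValueError(f"invalid status values: {sorted(bad_status)}")
        bad_stratum = set(df["stratum"].unique()) - {s.value for s in Stratum}
        if bad_stratum:
            raise ValueError(f"invalid stratum values: {sorted(bad_stratum)}")
        for snp in snp_ids:
            col = pd.to_numeric(df[snp], errors="coerce")
            valid = col.dropna()
            bad = valid[~valid.isin([0, 1, 2])]
            if len(bad):
                row = int(bad.index[0])
                raise ValueError(
                    f"invalid dosage {bad.iloc[0]!r} for SNP {snp} at row {row}"
                )
            df[snp] = col.astype(float)
        if "survival_time" in df.columns:
            t = pd.to_numeric(df["survival_time"], errors="coerce")
            if (t.dropna() <= 0).any():
                raise ValueError("survival_time must be positive where present")
        if "stage" in df.columns:
            st = pd.to_numeric(df["stage"], errors="coerce").dropna()
            if len(st) and not st.isin([1, 2, 3, 4]).all():
                raise ValueError("stage must be in {1,2,3,4}")
        self.df = df
        self.snp_ids = list(snp_ids)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortTable):
            return NotImplemented
        if self.snp_ids != other.snp_ids:
            return False
        a = self.df.reset_index(drop=True)
        b = other.df.reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False, check_like=True)
        except AssertionError:
            return False
        return True

    def subset(self, *, status: CaseStatus | None = None, stratum: Stratum | None = None) -> "CohortTable":
        df = self.df
        if status is not None:
            df = df[df["status"] == status.value]
        if stratum is not None:
            df = df[df["stratum"] == stratum.value]
        return CohortTable(df, self.snp_ids)

    def dosages(self, snps: Sequence[str] | None = None, complete_only: bool = False) -> np.ndarray:
        """n x L minor-allele dosage matrix (NaN = missing)."""
        snps = list(snps) if snps is not None else self.snp_ids
        mat = self.df[snps].to_numpy(dtype=float)
        if complete_only:
            mat = mat[~np.isnan(mat).any(axis=1)]
        return mat

    def genotype_counts(self, snp_id: str, stratum: Stratum) -> StratifiedGenotypeCounts:
        """Collapse individual dosages into a stratified 2x3 count table.

        Individuals missing the genotype are excluded (pairwise deletion).
        The SNP definition is synthesised with placeholder alleles when the
        table does not carry allele metadata.
        """
        snp = SnpDef(snp_id, gene="", alleles=("A", "B"))
        sub = self.df[self.df["stratum"] == stratum.value]
        out = {}
        for status in CaseStatus:
            dos = pd.to_numeric(sub.loc[sub["status"] == status.value, snp_id], errors="coerce").dropna()
            out[status] = tuple(int((dos == d).sum()) for d in (2, 1, 0))
        return StratifiedGenotypeCounts(snp, stratum, out[CaseStatus.CASE], out[CaseStatus.CONTROL])


@dataclass
class ResultRecord:
    """Serializable result of one analysis, with estimates and p-values."""

    analysis: str
    estimates: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    ci: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.p_values.items():
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"p-value {k}={v} outside [0,1]")

    def to_json(self) -> str:
        return json.dumps(
            {
                "analysis": self.analysis,
                "estimates": self.estimates,
                "statistics": self.statistics,
                "p_values": self.p_values,
                "ci": self.ci,
                "metadata": self.metadata,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "ResultRecord":
        d = json.loads(text)
        return cls(
            analysis=d["analysis"],
            estimates=d.get("estimates", {}),
            statistics=d.get("statistics", {}),
            p_values=d.get("p_values", {}),
            ci=d.get("ci", {}),
            metadata=d.get("metadata", {}),
        )
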