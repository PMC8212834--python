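"""Cohort table I/O (TSV dialect) and VCF genotype import.

TSV dialect: UTF-8, tab-separated, ``.`` for missing, header required.
Column order: ``id status stratum`` then any clinical columns, then one
column per rsID holding minor-allele dosages.
"""

from __future__ import annotations

import sys
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .types import CLINICAL_COLUMNS, CohortTable

MISSING = "."


class CohortFormatError(ValueError):
    """Raised for a malformed cohort file header or body."""


def _split_columns(columns: Sequence[str]) -> tuple[list[str], list[str]]:
    meta = [c for c in columns if c in CohortTable.REQUIRED or c in CLINICAL_COLUMNS]
    snps = [c for c in columns if c not in meta]
    return meta, snps


def read_cohort_table(path: str | Path, dialect: dict | None = None) -> CohortTable:
    """Read an individual-level cohort TSV.

    Parameters
    ----------
    path : path
        TSV file with at least ``id``, ``status``, ``stratum`` and one SNP
        column. ``.`` denotes a missing value; missing genotypes are kept
        as missing, never dropped.
    dialect : dict, optional
        Overrides, e.g. ``{"sep": ",", "missing": "NA"}``.

    Raises
    ------
    CohortFormatError
        On a malformed header (missing required column) naming the column.
    ValueError
        On a dosage outside {0, 1, 2}, citing the offending row.
    """
    opts = {"sep": "\t", "missing": MISSING}
    opts.update(dialect or {})
    df = pd.read_csv(path, sep=opts["sep"], dtype=str, na_values=[opts["missing"]],
                     keep_default_na=False)
    for col in CohortTable.REQUIRED:
        if col not in df.columns:
            raise CohortFormatError(f"malformed header: required column '{col}' absent")
    meta, snps = _split_columns(df.columns)
    if not snps:
        raise CohortFormatError("malformed header: no SNP columns found")
    for col in ("age_at_diagnosis", "pack_years", "stage", "ecog", "survival_time"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("surgery", "event"):
        if col in df.columns:
            df[col] = df[col].map({"1": True, "0": False, "True": True, "False": False})
    for snp in snps:
        raw = df[snp]
        num = pd.to_numeric(raw, errors="coerce")
        bad = raw.notna() & num.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric dosage {raw[bad].iloc[0]!r} for SNP {snp} at row {row}")
        df[snp] = num
    return CohortTable(df, snps)


def write_cohort_table(table: CohortTable, path: str | Path, dialect: dict | None = None) -> None:
    """Write a cohort table in the TSV dialect; inverse of read_cohort_table."""
    opts = {"sep": "\t", "missing": MISSING}
    opts.update(dialect or {})
    df = table.df.copy()
    for col in ("surgery", "event"):
        if col in df.columns:
            df[col] = df[col].map({True: "1", False: "0"})
    for snp in table.snp_ids:
        df[snp] = df[snp].map(lambda v: opts["missing"] if pd.isna(v) else str(int(v)))
    df.to_csv(path, sep=opts["sep"], index=False, na_rep=opts["missing"])


def import_vcf_genotypes(path: str | Path, snp_ids: Sequence[str]) -> pd.DataFrame:
    """Import diploid genotypes for the requested rsIDs from a VCF.

    Returns a DataFrame indexed by sample with one minor-allele dosage
    column per found rsID; the minor allele is estimated from the cohort
    itself (the allele with frequency <= 0.5 among called genotypes).
    ``./.`` genotypes become missing. Multi-allelic sites raise; rsIDs
    absent from the VCF are reported in a warning and omitted.
    """
    from cyvcf2 import VCF

    wanted = set(snp_ids)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for rec in vcf:
        if rec.ID not in wanted:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"{rec.ID}: multi-allelic site; only biallelic SNPs supported")
        # gt_types: 0=hom-ref, 1=het, 2=hom-alt(3 in cyvcf2 is hom-alt), 2=unknown
        alt_dosage = np.full(len(samples), np.nan)
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            if a < 0 or b < 0:
                continue
            alt_dosage[i] = (a > 0) + (b > 0)
        called = alt_dosage[~np.isnan(alt_dosage)]
        if len(called):
            alt_freq = called.sum() / (2 * len(called))
            # dosage counts the cohort-estimated minor allele
            dosage = alt_dosage if alt_freq <= 0.5 else 2 - alt_dosage
        else:
            dosage = alt_dosage
        columns[rec.ID] = dosage
    absent = sorted(wanted - set(columns))
    if absent:
        warnings.warn(f"rsIDs not found in VCF, omitted: {absent}")
    return pd.DataFrame(columns, index=samples)


def write_results(records, path: str | Path) -> None:
    """Serialize ResultRecords to newline-delimited JSON."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def log(msg: str, verbose: bool = True) -> None:
    if verbose:
        print(msg, file=sys.stderr)
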