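"""Bundled genotype count tables for the six-SNP APM panel.

The published study genotyped five ERAP1 SNPs and one ERAP2 SNP in Polish
NSCLC patients and healthy controls, each stratified into smokers and
never-smokers. The per-stratum 2x3 genotype count tables below are the atoms
every association statistic in :mod:`apmstrata.association` is computed from.

Counts are stored ``(minor-hom, het, major-hom)`` as printed. Row totals
differ across SNPs because individuals failing a genotyping assay are
excluded per-SNP.
"""

from __future__ import annotations

from .types import SnpDef, StratifiedGenotypeCounts, Stratum

# (major, minor) allele per SNP; minor allele defined from the full control
# group, matching the minor-hom vs major-hom OR orientation of the tables.
PANEL: tuple[SnpDef, ...] = (
    SnpDef("rs26653", "ERAP1", ("G", "C")),
    SnpDef("rs26618", "ERAP1", ("T", "C")),
    SnpDef("rs2287987", "ERAP1", ("T", "C")),
    SnpDef("rs30187", "ERAP1", ("C", "T")),
    SnpDef("rs27044", "ERAP1", ("C", "G")),
    SnpDef("rs2248374", "ERAP2", ("G", "A")),
)

_SNPS = {s.snp_id: s for s in PANEL}

# snp -> stratum -> (cases (minor-hom, het, major-hom), controls (same))
_COUNTS = {
    "rs26653": {
        Stratum.SMOKERS: ((24, 158, 205), (4, 73, 96)),
        Stratum.NEVER_SMOKERS: ((3, 17, 37), (16, 67, 73)),
    },
    "rs26618": {
        Stratum.SMOKERS: ((21, 158, 210), (12, 73, 86)),
        Stratum.NEVER_SMOKERS: ((6, 19, 32), (6, 50, 100)),
    },
    "rs2287987": {
        Stratum.SMOKERS: ((19, 121, 228), (15, 56, 100)),
        Stratum.NEVER_SMOKERS: ((4, 25, 28), (5, 49, 102)),
    },
    "rs30187": {
        Stratum.SMOKERS: ((41, 174, 175), (14, 72, 85)),
        Stratum.NEVER_SMOKERS: ((5, 21, 31), (31, 68, 57)),
    },
    "rs27044": {
        Stratum.SMOKERS: ((28, 147, 212), (8, 61, 102)),
        Stratum.NEVER_SMOKERS: ((2, 21, 34), (21, 57, 77)),
    },
    "rs2248374": {
        Stratum.SMOKERS: ((95, 189, 100), (38, 92, 41)),
        Stratum.NEVER_SMOKERS: ((15, 26, 16), (33, 78, 45)),
    },
}

#: Printed per-SNP combined P* values (both-strata 2-df test); the five
#: ERAP1 entries are the inputs of the gene-level global test.
PSTAR_PRINTED = {
    "rs26653": 0.011,
    "rs26618": 0.182,
    "rs2287987": 0.036,
    "rs30187": 0.017,
    "rs27044": 0.069,
    "rs2248374": 0.861,
}


def builtin_table2_counts() -> list[StratifiedGenotypeCounts]:
    """The 12 bundled stratified genotype tables (6 SNPs x 2 strata)."""
    out = []
    for snp in PANEL:
        for stratum in (Stratum.SMOKERS, Stratum.NEVER_SMOKERS):
            cases, controls = _COUNTS[snp.snp_id][stratum]
            out.append(StratifiedGenotypeCounts(snp, stratum, cases, controls))
    return out


def get_counts(snp_id: str, stratum: Stratum) -> StratifiedGenotypeCounts:
    """Fetch one bundled table by rsID and smoking stratum."""
    cases, controls = _COUNTS[snp_id][stratum]
    return StratifiedGenotypeCounts(_SNPS[snp_id], stratum, cases, controls)
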