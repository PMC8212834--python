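"""Per-stratum genotype association statistics and combined tests.

Implements the count-based statistics of a smoking-stratified case-control
SNP study: continuity-corrected genotype odds ratios with Woolf or bootstrap
confidence intervals, the Hardy-Weinberg disequilibrium coefficient f with
chi-square and exact tests, the 1-df trend (logistic score) test per
stratum, the 2-df combined per-SNP statistic P*, the Fisher-style gene-level
global test on 2L df, and the Mantel-Haenszel common odds ratio with
Breslow-Day homogeneity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CaseStatus, SnpDef, StratifiedGenotypeCounts, Stratum


class Comparison(str, Enum):
    HET_VS_REF = "het_vs_ref"
    HOM_VS_REF = "hom_vs_ref"


@dataclass
class ORResult:
    """Odds ratio for one genotype comparison (exposed vs major-hom)."""

    comparison: str
    or_value: float
    log_or: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str | None = None
    corrected: bool = True
    cells: tuple[float, float, float, float] = (np.nan,) * 4  # a, b, c, d

    def __post_init__(self) -> None:
        if not self.or_value > 0:
            raise ValueError("odds ratio must be positive")


@dataclass
class HWEResult:
    f: float
    p_c: float
    p_cc: float
    chi2: float
    p_value: float
    n: int
    method: str = "chi2"
    flag: str | None = None


@dataclass
class CombinedTestResult:
    per_stratum_chi2: tuple[float, float]
    pstar_stat: float
    pstar_p: float


@dataclass
class MHResult:
    or_mh: float
    ci: tuple[float, float]
    breslow_stat: float
    p_mh: float
    n_strata: int


@dataclass
class GeneGlobalResult:
    gene: str
    L: int
    stat: float
    df: int
    p_value: float


def _cells(counts: StratifiedGenotypeCounts, comparison: Comparison) -> tuple[int, int, int, int]:
    """Slice the 2x2 comparison cells: a=cases-exposed, b=cases-ref,
    c=controls-exposed, d=controls-ref (ref = major-hom)."""
    exp_idx = 1 if comparison is Comparison.HET_VS_REF else 0  # counts are (minor-hom, het, major-hom)
    a = counts.case_counts[exp_idx]
    b = counts.case_counts[2]
    c = counts.control_counts[exp_idx]
    d = counts.control_counts[2]
    return a, b, c, d


def genotype_or(
    counts: StratifiedGenotypeCounts,
    comparison: Comparison | str,
    correction: bool = True,
) -> ORResult:
    """Genotype odds ratio against the major-homozygote reference.

    With ``correction`` (Haldane-Anscombe, the default) 0.5 is added to all
    four cells unconditionally, which is what reproduces the published
    values on small tables.
    """
    comparison = Comparison(comparison)
    a, b, c, d = _cells(counts, comparison)
    delta = 0.5 if correction else 0.0
    if not correction and min(a, b, c, d) == 0:
        raise ZeroDivisionError(
            "zero cell in 2x2 table; enable the continuity correction (correction=True)"
        )
    or_value = ((a + delta) * (d + delta)) / ((b + delta) * (c + delta))
    return ORResult(
        comparison=comparison.value,
        or_value=or_value,
        log_or=math.log(or_value),
        corrected=correction,
        cells=(a, b, c, d),
    )


def or_ci(
    result: ORResult,
    counts: StratifiedGenotypeCounts | None = None,
    method: str = "woolf",
    reps: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> ORResult:
    """Attach a 95% confidence interval to an odds-ratio result.

    woolf
        exp(ln OR +- z * sqrt(sum 1/(cell + delta))), delta matching the
        correction used for the point estimate.
    bootstrap
        Percentile interval from resampling individuals within the case and
        control groups (multinomial over the two comparison cells), with
        0.5 added inside every resample so empty cells stay finite.
    """
    a, b, c, d = result.cells
    delta = 0.5 if result.corrected else 0.0
    z = stats.norm.ppf(1 - alpha / 2)
    if method == "woolf":
        se = math.sqrt(sum(1.0 / (x + delta) for x in (a, b, c, d)))
        lo, hi = math.exp(result.log_or - z * se), math.exp(result.log_or + z * se)
    elif method == "bootstrap":
        if reps < 1000:
            raise ValueError("bootstrap requires reps >= 1000")
        rng = np.random.default_rng(seed)
        n_case, n_ctrl = int(a + b), int(c + d)
        p_case = a / n_case
        p_ctrl = c / n_ctrl
        a_r = rng.binomial(n_case, p_case, size=reps)
        c_r = rng.binomial(n_ctrl, p_ctrl, size=reps)
        ors = ((a_r + 0.5) * (n_ctrl - c_r + 0.5)) / ((n_case - a_r + 0.5) * (c_r + 0.5))
        lo, hi = np.quantile(ors, [alpha / 2, 1 - alpha / 2])
    else:
        raise ValueError(f"unknown CI method: {method}")
    result.ci_low, result.ci_high, result.ci_method = float(lo), float(hi), method
    return result


def additive_prediction(het_or: float) -> float:
    """Minor-hom vs major-hom OR predicted by a per-allele (additive) model:
    the square of the heterozygote OR."""
    if het_or <= 0:
        raise ValueError("het_or must be positive")
    return het_or ** 2


def hwe(counts: Sequence[int], method: str = "chi2") -> HWEResult:
    """Hardy-Weinberg disequilibrium coefficient f and test.

    ``counts`` is a genotype triple ordered (minor-hom, het, major-hom).
    f = (p_cc - p_c^2) / (p_c (1 - p_c)) with p_c the minor allele frequency
    and p_cc the minor-homozygote frequency; f < 0 iff homozygote deficiency.

    chi2 : statistic n*f^2 on 1 df.
    exact : Levene-Haldane exact test over heterozygote counts.
    """
    cc, het, mm = (int(x) for x in counts)
    n = cc + het + mm
    if n <= 0:
        raise ValueError("empty genotype table")
    n_minor = 2 * cc + het
    if n_minor == 0 or n_minor == 2 * n:
        return HWEResult(np.nan, n_minor / (2 * n), cc / n, np.nan, np.nan, n,
                         method=method, flag="monomorphic")
    p_c = n_minor / (2 * n)
    p_cc = cc / n
    f = (p_cc - p_c ** 2) / (p_c * (1 - p_c))
    chi2 = n * f ** 2
    if method == "chi2":
        p = float(stats.chi2.sf(chi2, df=1))
    elif method == "exact":
        p = _hwe_exact_p(n, n_minor, het)
    else:
        raise ValueError(f"unknown HWE method: {method}")
    return HWEResult(f=float(f), p_c=p_c, p_cc=p_cc, chi2=float(chi2), p_value=p, n=n,
                     method=method)


def _hwe_exact_p(n: int, n_minor: int, het_obs: int) -> float:
    """Levene-Haldane exact HWE p: total probability of heterozygote counts
    no more probable than the observed one, conditional on allele counts."""
    n_major = 2 * n - n_minor
    hets = range(n_minor % 2, min(n_minor, n_major) + 1, 2)
    lg = math.lgamma

    def logprob(h: int) -> float:
        cc = (n_minor - h) // 2
        mm = (n_major - h) // 2
        return (
            lg(n + 1) - lg(cc + 1) - lg(h + 1) - lg(mm + 1)
            + h * math.log(2.0)
            + lg(n_minor + 1) + lg(n_major + 1) - lg(2 * n + 1)
        )

    logs = {h: logprob(h) for h in hets}
    m = max(logs.values())
    probs = {h: math.exp(v - m) for h, v in logs.items()}
    total = sum(probs.values())
    obs = probs[het_obs]
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(1.0, p)


def score_test_1df(counts: StratifiedGenotypeCounts) -> tuple[float, float]:
    """Cochran-Armitage trend test with additive dosage scores (0,1,2).

    Identical to the score test of logistic regression of case status on
    minor-allele dosage. Returns (chi-square statistic on 1 df, p-value).
    Zero dosage variance gives (0, 1).
    """
    case = counts.dosage_counts(CaseStatus.CASE)
    ctrl = counts.dosage_counts(CaseStatus.CONTROL)
    s = np.array([0.0, 1.0, 2.0])
    n = case + ctrl
    N = n.sum()
    R = case.sum()
    if R == 0 or R == N:
        raise ValueError("both case and control groups must be non-empty")
    sbar = (n * s).sum() / N
    V = R * (N - R) / N ** 2 * (n * (s - sbar) ** 2).sum()
    if V <= 0:
        return 0.0, 1.0
    U = (s * (case - n * R / N)).sum()
    stat = float(U * U / V)
    return stat, float(stats.chi2.sf(stat, df=1))


def pstar(
    smoker_counts: StratifiedGenotypeCounts,
    never_smoker_counts: StratifiedGenotypeCounts,
) -> CombinedTestResult:
    """Combined per-SNP test over both smoking strata.

    The two per-stratum 1-df trend statistics are summed and referred to a
    chi-square distribution on k = 2 degrees of freedom; the tail
    probability is the P* value reported per SNP.
    """
    s1, _ = score_test_1df(smoker_counts)
    s2, _ = score_test_1df(never_smoker_counts)
    stat = s1 + s2
    return CombinedTestResult((s1, s2), stat, float(stats.chi2.sf(stat, df=2)))


def gene_global_test(pstar_values: Sequence[float], gene: str = "") -> GeneGlobalResult:
    """Gene-level global association test from per-SNP P* values.

    Fisher-style combination: statistic -2 * sum(ln P*_l) referred to a
    chi-square distribution on 2L df, L the number of SNPs in the gene.
    """
    ps = list(pstar_values)
    if not ps:
        raise ValueError("need at least one P* value")
    if any(p <= 0 or p > 1 for p in ps):
        raise ValueError("P* values must lie in (0, 1]; zero gives an infinite statistic")
    stat = -2.0 * sum(math.log(p) for p in ps)
    df = 2 * len(ps)
    return GeneGlobalResult(gene=gene, L=len(ps), stat=float(stat), df=df,
                            p_value=float(stats.chi2.sf(stat, df=df)))


def mantel_haenszel(tables: Iterable[np.ndarray]) -> MHResult:
    """Mantel-Haenszel common odds ratio across 2x2 strata.

    Each table is [[a, b], [c, d]] (cases exposed/ref; controls
    exposed/ref). The point estimate is sum(a_i d_i / n_i)/sum(b_i c_i / n_i),
    the CI uses the Robins-Breslow-Greenland variance, and homogeneity is
    the Breslow-Day statistic with Tarone correction. Strata with an empty
    margin are dropped with a warning.
    """
    kept = []
    for t in tables:
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or t.sum() <= 0:
            raise ValueError("each stratum must be a 2x2 table with positive total")
        if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
            warnings.warn("dropping stratum with an empty margin")
            continue
        kept.append(t)
    if not kept:
        raise ValueError("no usable strata")
    import statsmodels.api as sm

    st = sm.stats.StratifiedTable(kept)
    or_mh = float(st.oddsratio_pooled)
    lo, hi = st.oddsratio_pooled_confint()
    if len(kept) == 1:
        bd_stat, bd_p = 0.0, 1.0
    else:
        res = st.test_equal_odds(adjust=True)
        bd_stat, bd_p = float(res.statistic), float(res.pvalue)
    return MHResult(or_mh=or_mh, ci=(float(lo), float(hi)), breslow_stat=bd_stat,
                    p_mh=bd_p, n_strata=len(kept))


def mantel_haenszel_from_counts(
    per_stratum: Sequence[StratifiedGenotypeCounts], comparison: Comparison | str
) -> MHResult:
    """MH estimate for one genotype comparison pooled over smoking strata.

    The third genotype is excluded from each stratum's 2x2 table, matching
    the per-comparison orientation of the published tables.
    """
    comparison = Comparison(comparison)
    tables = []
    for counts in per_stratum:
        a, b, c, d = _cells(counts, comparison)
        tables.append(np.array([[a, b], [c, d]], dtype=float))
    return mantel_haenszel(tables)


def run_association_scan(
    counts: Sequence[StratifiedGenotypeCounts],
    ci_method: str = "woolf",
    reps: int = 2000,
    seed: int | None = None,
    hwe_method: str = "chi2",
) -> dict[str, pd.DataFrame]:
    """Full per-SNP association scan over all strata, Table-2 style.

    Returns ``{"snp_table": ..., "gene_table": ...}``; the SNP table has one
    row per SNP with per-stratum het/hom ORs and CIs, HWE f and p per group
    per stratum, P*, and OR.MH with homogeneity p per comparison; the gene
    table carries the 2L-df global statistic per gene. Per-SNP failures are
    flagged in an ``error`` column rather than aborting the scan.
    """
    by_snp: dict[str, dict[Stratum, StratifiedGenotypeCounts]] = {}
    snp_defs: dict[str, SnpDef] = {}
    for c in counts:
        by_snp.setdefault(c.snp.snp_id, {})[c.stratum] = c
        snp_defs[c.snp.snp_id] = c.snp

    order = sorted(snp_defs, key=lambda s: (snp_defs[s].gene, s))
    rows = []
    pstar_by_gene: dict[str, list[tuple[str, float]]] = {}
    for i, snp_id in enumerate(order):
        snp = snp_defs[snp_id]
        row: dict[str, object] = {"gene": snp.gene, "snp": snp_id, "error": ""}
        try:
            strata = by_snp[snp_id]
            for stratum, tag in ((Stratum.SMOKERS, "s"), (Stratum.NEVER_SMOKERS, "ns")):
                tab = strata[stratum]
                for comp, ctag in ((Comparison.HET_VS_REF, "het"), (Comparison.HOM_VS_REF, "hom")):
                    res = or_ci(genotype_or(tab, comp), tab, method=ci_method,
                                reps=reps, seed=None if seed is None else seed + i)
                    row[f"or_{ctag}_{tag}"] = res.or_value
                    row[f"ci_{ctag}_{tag}"] = (res.ci_low, res.ci_high)
                for status, gtag in ((CaseStatus.CASE, "case"), (CaseStatus.CONTROL, "control")):
                    h = hwe(tab.counts(status), method=hwe_method)
                    row[f"f_{gtag}_{tag}"] = h.f
                    row[f"hwe_p_{gtag}_{tag}"] = h.p_value
            comb = pstar(strata[Stratum.SMOKERS], strata[Stratum.NEVER_SMOKERS])
            row["pstar"] = comb.pstar_p
            for comp, ctag in ((Comparison.HET_VS_REF, "het"), (Comparison.HOM_VS_REF, "hom")):
                mh = mantel_haenszel_from_counts(
                    [strata[Stratum.SMOKERS], strata[Stratum.NEVER_SMOKERS]], comp)
                row[f"or_mh_{ctag}"] = mh.or_mh
                row[f"p_mh_{ctag}"] = mh.p_mh
            pstar_by_gene.setdefault(snp.gene, []).append((snp_id, comb.pstar_p))
        except Exception as exc:  # flagged row, scan continues
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)

    gene_rows = []
    for gene in sorted(pstar_by_gene):
        entries = pstar_by_gene[gene]
        res = gene_global_test([p for _, p in entries], gene=gene)
        gene_rows.append({"gene": gene, "L": res.L, "chi2": res.stat, "df": res.df,
                          "p_value": res.p_value})
    return {"snp_table": pd.DataFrame(rows), "gene_table": pd.DataFrame(gene_rows)}
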