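"""EM haplotype frequency estimation, case-control haplotype effects and LD.

Phase-unknown multi-SNP genotypes are resolved by the standard EM algorithm
for haplotype frequencies: the E-step computes the posterior probability of
each compatible haplotype pair per individual assuming random (Hardy-
Weinberg) pairing within group, the M-step replaces frequencies with
expected haplotype counts over 2n chromosomes. The genotype log-likelihood
is non-decreasing across iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CaseStatus, CohortTable, SnpDef, Stratum


@dataclass
class EMResult:
    """Haplotype frequencies (keyed by allele string) and fit diagnostics."""

    frequencies: dict[str, float]
    log_likelihood: float
    n_iter: int
    converged: bool
    n_individuals: int
    panel: tuple[str, ...]


@dataclass
class HaplotypeTable:
    """Per-haplotype case/control frequencies and effect sizes."""

    table: pd.DataFrame  # columns: haplotype, freq_cases, freq_controls, or_value, log_or, ci_low, ci_high
    chi2: float
    df: int
    p_value: float
    total_cases: float
    total_controls: float


@dataclass
class LDResult:
    snp_pair: tuple[str, str]
    r2: float
    d_prime: float
    flag: str | None = None


def _hap_string(hap: tuple[int, ...], panel: Sequence[SnpDef] | None, L: int) -> str:
    if panel is None:
        return "-".join(str(a) for a in hap)
    return "-".join(snp.alleles[a] for snp, a in zip(panel, hap))


def _compatible_pairs(geno: tuple[int, ...]) -> list[tuple[tuple[int, ...], tuple[int, ...]]]:
    """All unordered haplotype pairs consistent with a dosage genotype."""
    het_idx = [i for i, g in enumerate(geno) if g == 1]
    base = [g // 2 if g != 1 else None for g in geno]
    if not het_idx:
        h = tuple(int(b) for b in base)
        return [(h, h)]
    pairs = []
    # fix the first het site on haplotype 1 to avoid double counting
    for assign in product((0, 1), repeat=len(het_idx) - 1):
        bits = (0,) + assign
        h1, h2 = list(base), list(base)
        for i, b in zip(het_idx, bits):
            h1[i], h2[i] = b, 1 - b
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


def em_haplotype_frequencies(
    cohort: CohortTable | np.ndarray,
    snps: Sequence[str] | None = None,
    *,
    status: CaseStatus | None = None,
    stratum: Stratum | None = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    start: str = "counting",
    panel_defs: Sequence[SnpDef] | None = None,
) -> EMResult:
    """Estimate haplotype frequencies from unphased genotypes by EM.

    Parameters
    ----------
    cohort : CohortTable or dosage matrix
        Individuals; those incomplete over the panel are excluded.
    snps : sequence of rsID, optional
        SNP panel (column order defines haplotype positions); defaults to
        all SNPs of the cohort.
    status, stratum : optional selectors applied before estimation.
    start : {"counting", "uniform"}
        "counting" initialises at the product of per-site allele
        frequencies; "uniform" gives all compatible haplotypes equal mass.
        Symmetric ties are left at their symmetric fixed point.
    panel_defs : optional SnpDef sequence to render allele-string keys;
        otherwise haplotypes are keyed by 0/1 allele indices.

    Returns an :class:`EMResult`; ``converged`` is False when ``max_iter``
    was reached before the maximum frequency change fell below ``tol``.
    """
    if isinstance(cohort, CohortTable):
        sub = cohort.subset(status=status, stratum=stratum)
        snps = list(snps) if snps is not None else sub.snp_ids
        mat = sub.dosages(snps, complete_only=True)
    else:
        mat = np.asarray(cohort, dtype=float)
        mat = mat[~np.isnan(mat).any(axis=1)]
        snps = list(snps) if snps is not None else [f"snp{i}" for i in range(mat.shape[1])]
    n, L = mat.shape if mat.ndim == 2 else (0, 0)
    if n == 0:
        raise ValueError("no individuals with complete genotypes over the panel")
    if tol <= 0:
        raise ValueError("tol must be positive")

    genos, counts = np.unique(mat.astype(int), axis=0, return_counts=True)
    pair_lists = [_compatible_pairs(tuple(g)) for g in genos]

    hap_index: dict[tuple[int, ...], int] = {}
    for pairs in pair_lists:
        for h1, h2 in pairs:
            for h in (h1, h2):
                hap_index.setdefault(h, len(hap_index))
    haps = list(hap_index)
    H = len(haps)

    if start == "uniform":
        freq = np.full(H, 1.0 / H)
    elif start == "counting":
        # product of per-site allele frequencies, restricted to seen haplotypes
        allele_freq = mat.mean(axis=0) / 2.0
        freq = np.array([
            math.prod(allele_freq[i] if a == 1 else 1 - allele_freq[i] for i, a in enumerate(h))
            for h in haps
        ])
        if freq.sum() <= 0:
            freq = np.full(H, 1.0 / H)
        freq = freq / freq.sum()
    else:
        raise ValueError(f"unknown start: {start}")

    # index arrays per genotype class for vectorised E-steps
    class_pairs = [
        (np.array([hap_index[h1] for h1, _ in pairs]),
         np.array([hap_index[h2] for _, h2 in pairs]),
         np.array([1.0 if h1 == h2 else 2.0 for h1, h2 in pairs]))
        for pairs in pair_lists
    ]

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = np.zeros(H)
        ll = 0.0
        for cnt, (i1, i2, mult) in zip(counts, class_pairs):
            w = mult * freq[i1] * freq[i2]
            tot = w.sum()
            if tot <= 0:
                continue
            ll += cnt * math.log(tot)
            w = w / tot * cnt
            np.add.at(new, i1, w)
            np.add.at(new, i2, w)
        new = new / (2 * n)
        delta = np.max(np.abs(new - freq))
        freq = new
        loglik = ll
        if delta < tol:
            converged = True
            break

    frequencies = {
        _hap_string(h, panel_defs, L): float(freq[hap_index[h]])
        for h in haps
        if freq[hap_index[h]] > 0
    }
    return EMResult(frequencies=frequencies, log_likelihood=float(loglik), n_iter=it,
                    converged=converged, n_individuals=n, panel=tuple(snps))


def genotype_log_likelihood(mat: np.ndarray, freq: Mapping[tuple[int, ...], float]) -> float:
    """Log-likelihood of unphased genotypes given haplotype frequencies
    under random pairing (used as an independent check of the EM optimum)."""
    mat = np.asarray(mat, dtype=float)
    mat = mat[~np.isnan(mat).any(axis=1)].astype(int)
    ll = 0.0
    for g in mat:
        tot = 0.0
        for h1, h2 in _compatible_pairs(tuple(g)):
            mult = 1.0 if h1 == h2 else 2.0
            tot += mult * freq.get(h1, 0.0) * freq.get(h2, 0.0)
        if tot <= 0:
            return -np.inf
        ll += math.log(tot)
    return ll


def haplotype_case_control(
    freq_cases: Mapping[str, float],
    freq_controls: Mapping[str, float],
    n_cases: int,
    n_controls: int,
    reps: int = 2000,
    seed: int | None = None,
    min_freq: float = 0.0,
    cohort: CohortTable | None = None,
    snps: Sequence[str] | None = None,
    stratum: Stratum | None = None,
    panel_defs: Sequence[SnpDef] | None = None,
) -> HaplotypeTable:
    """Case-control haplotype effect table from EM frequency estimates.

    Per haplotype the OR is the cross-product of expected chromosome counts
    (2n * freq vs the rest) with the 0.5 continuity correction. The overall
    distribution test is a chi-square over the haplotype x group
    expected-count table on (#haplotypes - 1) df. Haplotypes below
    ``min_freq`` in both groups are pooled into an explicit "other" row.

    Bootstrap CIs resample individuals and re-run the EM when ``cohort``
    (with ``snps``) is given; otherwise chromosomes are resampled
    multinomially from the estimated frequencies.
    """
    if reps < 1000:
        raise ValueError("reps must be >= 1000 for the bootstrap")
    universe = sorted(set(freq_cases) | set(freq_controls))
    fc = np.array([freq_cases.get(h, 0.0) for h in universe])
    fk = np.array([freq_controls.get(h, 0.0) for h in universe])
    present = (fc > 0) | (fk > 0)
    universe = [h for h, keep in zip(universe, present) if keep]
    fc, fk = fc[present], fk[present]

    keep = (fc >= min_freq) | (fk >= min_freq)
    if min_freq > 0 and not keep.all():
        labels = [h for h, k in zip(universe, keep) if k] + ["other"]
        fc = np.append(fc[keep], fc[~keep].sum())
        fk = np.append(fk[keep], fk[~keep].sum())
    else:
        labels = list(universe)

    ca = 2 * n_cases * fc   # expected case chromosomes per haplotype
    ko = 2 * n_controls * fk

    def _ors(ca_, ko_, nc, nk):
        a = ca_ + 0.5
        b = 2 * nc - ca_ + 0.5
        c = ko_ + 0.5
        d = 2 * nk - ko_ + 0.5
        return (a * d) / (b * c)

    ors = _ors(ca, ko, n_cases, n_controls)

    # distribution test over the expected-count contingency table
    obs = np.vstack([ca, ko])
    chi2, df = _contingency_chi2(obs)
    p_value = float(stats.chi2.sf(chi2, df=df)) if df > 0 else 1.0

    rng = np.random.default_rng(seed)
    boot = np.empty((reps, len(labels)))
    if cohort is not None:
        snps = list(snps) if snps is not None else cohort.snp_ids
        case_df = cohort.subset(status=CaseStatus.CASE, stratum=stratum).df
        ctrl_df = cohort.subset(status=CaseStatus.CONTROL, stratum=stratum).df
        for r in range(reps):
            bc = CohortTable(case_df.sample(len(case_df), replace=True,
                                            random_state=int(rng.integers(2**31))), snps)
            bk = CohortTable(ctrl_df.sample(len(ctrl_df), replace=True,
                                            random_state=int(rng.integers(2**31))), snps)
            ec = em_haplotype_frequencies(bc, snps, panel_defs=panel_defs, tol=1e-6)
            ek = em_haplotype_frequencies(bk, snps, panel_defs=panel_defs, tol=1e-6)
            bfc = _pooled_freq_vector(ec.frequencies, labels)
            bfk = _pooled_freq_vector(ek.frequencies, labels)
            boot[r] = _ors(2 * ec.n_individuals * bfc, 2 * ek.n_individuals * bfk,
                           ec.n_individuals, ek.n_individuals)
    else:
        pc = np.append(fc, max(0.0, 1 - fc.sum()))
        pk = np.append(fk, max(0.0, 1 - fk.sum()))
        bc = rng.multinomial(2 * n_cases, pc / pc.sum(), size=reps)[:, :-1].astype(float)
        bk = rng.multinomial(2 * n_controls, pk / pk.sum(), size=reps)[:, :-1].astype(float)
        boot = _ors(bc, bk, n_cases, n_controls)
    lo = np.quantile(boot, 0.025, axis=0)
    hi = np.quantile(boot, 0.975, axis=0)

    table = pd.DataFrame({
        "haplotype": labels,
        "freq_cases": fc,
        "freq_controls": fk,
        "or_value": ors,
        "log_or": np.log(ors),
        "ci_low": lo,
        "ci_high": hi,
    }).sort_values("freq_controls", ascending=False, kind="stable").reset_index(drop=True)
    return HaplotypeTable(table=table, chi2=float(chi2), df=int(df), p_value=p_value,
                          total_cases=float(fc.sum()), total_controls=float(fk.sum()))


def _pooled_freq_vector(freqs: Mapping[str, float], labels: Sequence[str]) -> np.ndarray:
    named = [l for l in labels if l != "other"]
    out = np.array([freqs.get(h, 0.0) for h in named])
    if "other" in labels:
        out = np.append(out, max(0.0, 1.0 - out.sum()))
    return out


def _contingency_chi2(obs: np.ndarray) -> tuple[float, int]:
    """Pearson chi-square on a 2 x H expected-count table, df = H - 1.

    Invariant to column (haplotype) ordering. Columns with zero total are
    dropped.
    """
    obs = obs[:, obs.sum(axis=0) > 0]
    H = obs.shape[1]
    if H < 2:
        return 0.0, 0
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    exp = row @ col / obs.sum()
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, H - 1


def haplotype_effect_plot_data(
    smokers: HaplotypeTable, never_smokers: HaplotypeTable
) -> pd.DataFrame:
    """Pair log ORs per haplotype in both strata, sorted by the
    never-smoker effect (ascending); negative log OR = protective."""
    s = smokers.table.set_index("haplotype")["log_or"]
    ns = never_smokers.table.set_index("haplotype")["log_or"]
    common = sorted(set(s.index) & set(ns.index))
    df = pd.DataFrame({
        "haplotype": common,
        "log_or_smokers": s.loc[common].to_numpy(),
        "log_or_never_smokers": ns.loc[common].to_numpy(),
    }).sort_values("log_or_never_smokers", kind="stable").reset_index(drop=True)
    df["effect_never_smokers"] = np.where(df["log_or_never_smokers"] < 0, "protective",
                                          np.where(df["log_or_never_smokers"] > 0,
                                                   "predisposing", "null"))
    return df


def ld_pair(
    cohort: CohortTable | np.ndarray,
    snp_a: str,
    snp_b: str,
    stratum: Stratum | None = None,
) -> LDResult:
    """Pairwise linkage disequilibrium from EM haplotype frequencies.

    D = p_AB - p_A p_B over the minor-allele indicators; r^2 = D^2 /
    (p_A p_a p_B p_b); D' = |D| / D_max. Monomorphic SNPs give a flagged
    undefined result.
    """
    em = em_haplotype_frequencies(cohort, [snp_a, snp_b], stratum=stratum)
    freqs = {tuple(int(x) for x in h.split("-")): f for h, f in em.frequencies.items()}
    p_ab = freqs.get((1, 1), 0.0)
    p_a = sum(f for h, f in freqs.items() if h[0] == 1)
    p_b = sum(f for h, f in freqs.items() if h[1] == 1)
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return LDResult((snp_a, snp_b), np.nan, np.nan, flag="monomorphic")
    D = p_ab - p_a * p_b
    r2 = D * D / (p_a * (1 - p_a) * p_b * (1 - p_b))
    d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b) if D > 0 else min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(D) / d_max if d_max > 0 else np.nan
    return LDResult((snp_a, snp_b), float(r2), float(min(d_prime, 1.0)))
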