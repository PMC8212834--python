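"""Synthetic stratified case-control cohorts with known ground truth.

Controls are formed by pairing two haplotypes drawn i.i.d. from the
configured frequency map (Hardy-Weinberg pairing); optional disequilibrium
f >= 0 is injected by copying the first haplotype with probability f, which
yields homozygote frequency p^2 + f p(1-p) per SNP. Case status follows a
logistic model whose per-genotype coefficients are the configured log odds
ratios per smoking stratum, and the cohort is sampled retrospectively (fixed
numbers of cases and controls per stratum) to match the case-control design.

Clinical outcome processes (age at diagnosis, ordinal stage, exponential
survival with uniform censoring, ordinal chemotherapy response) are layered
on the genotypes so every downstream model has a recoverable truth.

Default scale mirrors the published cohort: a six-SNP ERAP1/ERAP2 panel with
the control haplotype frequencies of the smokers' control column, 387/173
smoker cases/controls and 57/156 never-smoker cases/controls.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import table2
from .types import CaseStatus, CohortTable, SnpDef, Stratum


@dataclass
class ClinicalConfig:
    """Outcome-process parameters for simulate_clinical (units in brackets)."""

    aad_mean: float = 64.0          # age at diagnosis [years]
    aad_sd: float = 9.0
    # (snp_id, stratum value, dosage) -> additive AAD shift [years]
    aad_shifts: dict = field(default_factory=dict)
    male_prob: float = 0.694
    surgery_prob: float = 0.466
    evaluable_prob: float = 0.45    # chemotherapy-response evaluable
    stage_alpha: tuple = (-1.169, -0.502, 0.690)   # cumulative-logit thresholds
    stage_beta: dict = field(default_factory=dict)  # covariate -> coefficient
    survival_baseline_hazard: float = 0.0578        # [1/month], median ~12 mo
    survival_log_hrs: dict = field(default_factory=dict)
    censor_time: float = 24.0       # uniform censoring horizon [months]
    response_alpha: tuple = (-0.795, -0.282, 0.969)
    response_beta: dict = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Full generator configuration; ``seed`` is mandatory."""

    panel: tuple[SnpDef, ...]
    haplotype_freqs: dict[str, float]
    sample_sizes: dict[Stratum, tuple[int, int]]  # (n_cases, n_controls)
    genotype_effects: dict = field(default_factory=dict)  # snp -> {stratum: (or_het, or_hom)}
    hwe_f: float | None = None
    baseline_logit: float = 0.0
    clinical: ClinicalConfig = field(default_factory=ClinicalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.haplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")
        for snp, per_stratum in self.genotype_effects.items():
            for ors in per_stratum.values():
                if any(v <= 0 for v in ors):
                    raise ValueError(f"{snp}: odds ratios must be positive")
        for n_cases, n_controls in self.sample_sizes.values():
            if n_cases < 0 or n_controls < 0:
                raise ValueError("sample sizes must be non-negative")
        if self.hwe_f is not None and not (0.0 <= self.hwe_f <= 1.0):
            raise ValueError(
                "hwe_f must lie in [0, 1]: the haplotype-copy mixture construction "
                "cannot express heterozygote excess (f < 0)"
            )
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def config_hash(self) -> str:
        def _stringify(obj):
            if isinstance(obj, dict):
                return {str(k): _stringify(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_stringify(v) for v in obj]
            return obj

        payload = json.dumps(
            {
                "panel": [(s.snp_id, s.gene, s.alleles) for s in self.panel],
                "haplotype_freqs": self.haplotype_freqs,
                "sample_sizes": {k.value: v for k, v in self.sample_sizes.items()},
                "genotype_effects": {
                    s: {st.value if isinstance(st, Stratum) else st: list(v)
                        for st, v in d.items()}
                    for s, d in self.genotype_effects.items()
                },
                "hwe_f": self.hwe_f,
                "baseline_logit": self.baseline_logit,
                "clinical": _stringify(asdict(self.clinical)),
                "seed": self.seed,
            },
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SimulatedCohort:
    cohort: CohortTable
    truth: dict
    config: SimulationConfig


# Control haplotype frequencies (%) of the smokers' control column, used as
# the default population; the 0.7% residual mass is renormalised away.
DEFAULT_HAPLOTYPE_FREQS_PCT = {
    "G-C-T-C-C-A": 21.6,
    "G-T-C-C-C-A": 14.4,
    "C-T-T-T-G-G": 9.9,
    "G-T-C-C-C-G": 9.3,
    "G-T-T-T-G-G": 8.4,
    "G-T-T-C-C-G": 7.5,
    "G-C-T-C-C-G": 6.4,
    "C-T-T-C-C-G": 5.3,
    "G-T-T-T-G-A": 4.3,
    "C-T-T-T-C-A": 3.8,
    "G-T-T-C-C-A": 3.7,
    "C-T-T-T-C-G": 3.5,
    "C-T-T-C-C-A": 1.2,
}


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Configuration mimicking the published two-stratum six-SNP design."""
    total = sum(DEFAULT_HAPLOTYPE_FREQS_PCT.values())
    freqs = {h: v / total for h, v in DEFAULT_HAPLOTYPE_FREQS_PCT.items()}
    cfg = dict(
        panel=table2.PANEL,
        haplotype_freqs=freqs,
        sample_sizes={Stratum.SMOKERS: (387, 173), Stratum.NEVER_SMOKERS: (57, 156)},
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


def equilibrium_config(
    mafs: Sequence[float],
    sample_sizes: dict[Stratum, tuple[int, int]],
    seed: int,
    gene: str = "GENE",
    **overrides,
) -> SimulationConfig:
    """Config for a panel of SNPs in linkage equilibrium.

    Haplotype frequencies are the product of per-SNP allele frequencies, so
    the per-SNP tests are independent — the regime in which the gene-level
    Fisher-style combination is exactly calibrated.
    """
    from itertools import product as iproduct

    panel = tuple(SnpDef(f"rs{i + 1:03d}", gene, ("A", "B")) for i in range(len(mafs)))
    freqs: dict[str, float] = {}
    for combo in iproduct((0, 1), repeat=len(mafs)):
        f = 1.0
        for a, p in zip(combo, mafs):
            f *= p if a else 1.0 - p
        freqs["-".join("B" if a else "A" for a in combo)] = f
    total = sum(freqs.values())
    freqs = {k: v / total for k, v in freqs.items()}
    return SimulationConfig(panel=panel, haplotype_freqs=freqs,
                            sample_sizes=sample_sizes, seed=seed, **overrides)


def _hap_matrix(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """(H x L) 0/1 allele matrix and H-vector of frequencies."""
    panel = config.panel
    rows, probs = [], []
    for hap, freq in config.haplotype_freqs.items():
        alleles = hap.split("-")
        if len(alleles) != len(panel):
            raise ValueError(f"haplotype {hap} length != panel size")
        row = []
        for a, snp in zip(alleles, panel):
            if a not in snp.alleles:
                raise ValueError(f"haplotype {hap}: allele {a} not in {snp.snp_id}")
            row.append(snp.alleles.index(a))
        rows.append(row)
        probs.append(freq)
    return np.array(rows, dtype=np.int8), np.array(probs, dtype=float)


def _stratum_effects(config: SimulationConfig, stratum: Stratum) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (log OR het, log OR hom) arrays for a stratum."""
    L = len(config.panel)
    log_het = np.zeros(L)
    log_hom = np.zeros(L)
    for j, snp in enumerate(config.panel):
        per = config.genotype_effects.get(snp.snp_id, {})
        ors = per.get(stratum) or per.get(stratum.value)
        if ors is not None:
            log_het[j] = math.log(ors[0])
            log_hom[j] = math.log(ors[1])
    return log_het, log_hom


def _draw_stratum(
    rng: np.random.Generator, config: SimulationConfig, stratum: Stratum
) -> tuple[np.ndarray, np.ndarray]:
    """Retrospective sample: (case dosages, control dosages) for a stratum."""
    n_cases, n_controls = config.sample_sizes[stratum]
    haps, probs = _hap_matrix(config)
    log_het, log_hom = _stratum_effects(config, stratum)
    f = config.hwe_f or 0.0

    cases: list[np.ndarray] = []
    controls: list[np.ndarray] = []
    have_c = have_k = 0
    batch = max(4 * (n_cases + n_controls), 512)
    for _ in range(200):  # safety bound on pool batches
        if have_c >= n_cases and have_k >= n_controls:
            break
        i1 = rng.choice(len(probs), size=batch, p=probs)
        i2 = rng.choice(len(probs), size=batch, p=probs)
        if f > 0:
            copy = rng.random(batch) < f
            i2 = np.where(copy, i1, i2)
        dos = (haps[i1] + haps[i2]).astype(np.int8)
        logit = config.baseline_logit + (dos == 1) @ log_het + (dos == 2) @ log_hom
        is_case = rng.random(batch) < 1.0 / (1.0 + np.exp(-logit))
        cases.append(dos[is_case])
        controls.append(dos[~is_case])
        have_c += int(is_case.sum())
        have_k += int((~is_case).sum())
    case_dos = np.concatenate(cases)[:n_cases]
    ctrl_dos = np.concatenate(controls)[:n_controls]
    if len(case_dos) < n_cases or len(ctrl_dos) < n_controls:
        raise RuntimeError("could not fill case/control quotas; check baseline_logit")
    return case_dos, ctrl_dos


def simulate_genotypes(config: SimulationConfig) -> SimulatedCohort:
    """Generate a stratified case-control cohort of genotypes.

    Reproducible under ``config.seed``; the returned ``truth`` records the
    configured haplotype frequencies and effects alongside the data.
    """
    rng = np.random.default_rng(config.seed)
    snp_ids = [s.snp_id for s in config.panel]
    frames = []
    counter = 0
    for stratum in config.sample_sizes:
        case_dos, ctrl_dos = _draw_stratum(rng, config, stratum)
        for status, dos in ((CaseStatus.CASE, case_dos), (CaseStatus.CONTROL, ctrl_dos)):
            df = pd.DataFrame(dos.astype(float), columns=snp_ids)
            df.insert(0, "stratum", stratum.value)
            df.insert(0, "status", status.value)
            df.insert(0, "id", [f"ind{counter + i:05d}" for i in range(len(df))])
            counter += len(df)
            frames.append(df)
    full = pd.concat(frames, ignore_index=True)
    truth = {
        "haplotype_freqs": dict(config.haplotype_freqs),
        "genotype_effects": {
            s: {st.value if isinstance(st, Stratum) else st: list(v) for st, v in d.items()}
            for s, d in config.genotype_effects.items()
        },
        "hwe_f": config.hwe_f,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    return SimulatedCohort(CohortTable(full, snp_ids), truth, config)


def _covariate(df: pd.DataFrame, key: str, panel_ids: Sequence[str]) -> np.ndarray:
    """Resolve a covariate key against the cohort frame.

    Supported keys: an rsID (minor-allele dosage), ``<rsID>_carrier``,
    ``<rsID>_het``, plus ``male``, ``no_surgery``, ``stage``,
    ``age_at_diagnosis`` and ``smoker``.
    """
    if key in panel_ids:
        return df[key].to_numpy(dtype=float)
    if key.endswith("_carrier") and key[:-8] in panel_ids:
        return (df[key[:-8]].to_numpy(dtype=float) > 0).astype(float)
    if key.endswith("_het") and key[:-4] in panel_ids:
        return (df[key[:-4]].to_numpy(dtype=float) == 1).astype(float)
    if key == "male":
        return (df["sex"] == "male").to_numpy(dtype=float)
    if key == "no_surgery":
        return 1.0 - df["surgery"].astype(float).to_numpy()
    if key == "smoker":
        return (df["stratum"] == Stratum.SMOKERS.value).to_numpy(dtype=float)
    if key in df.columns:
        return df[key].to_numpy(dtype=float)
    raise KeyError(f"unknown covariate key: {key}")


def _ordinal_draw(rng, alpha: Sequence[float], xb: np.ndarray) -> np.ndarray:
    """Sample ordinal levels 1..len(alpha)+1 from a cumulative-logit model
    with P(Y <= r) = expit(alpha_r - xb) (positive xb shifts upward)."""
    cum = np.array([1.0 / (1.0 + np.exp(-(a - xb))) for a in alpha])  # (R-1, n)
    u = rng.random(xb.shape[0])
    return 1 + (u[None, :] > cum).sum(axis=0)


def simulate_clinical(sim: SimulatedCohort, config: SimulationConfig | None = None) -> SimulatedCohort:
    """Attach clinical covariates and outcomes to a simulated cohort.

    Cases receive age at diagnosis (normal, with configured genotype x
    stratum shifts), ordinal stage 1-4 and chemotherapy response from
    cumulative-logit models, surgery, and exponential survival with uniform
    censoring on (0, censor_time]. Controls keep genotypes and sex only.
    Uses a seed derived from the genotype seed so the two stages are
    independently reproducible.
    """
    config = config or sim.config
    cc = config.clinical
    rng = np.random.default_rng((config.seed + 1) * 104729 % 2**31)
    df = sim.cohort.df.copy()
    panel_ids = sim.cohort.snp_ids
    n = len(df)

    df["sex"] = np.where(rng.random(n) < cc.male_prob, "male", "female")
    is_case = (df["status"] == CaseStatus.CASE.value).to_numpy()
    m = int(is_case.sum())
    cases = df.loc[is_case]

    aad = rng.normal(cc.aad_mean, cc.aad_sd, size=m)
    for (snp_id, stratum, dosage), shift in cc.aad_shifts.items():
        stratum = stratum.value if isinstance(stratum, Stratum) else stratum
        mask = (cases["stratum"] == stratum) & (cases[snp_id] == dosage)
        aad = aad + np.where(mask.to_numpy(), shift, 0.0)
    df.loc[is_case, "age_at_diagnosis"] = np.round(aad, 1)

    xb_stage = np.zeros(m)
    for key, beta in cc.stage_beta.items():
        xb_stage += beta * _covariate(df.loc[is_case], key, panel_ids)
    df.loc[is_case, "stage"] = _ordinal_draw(rng, cc.stage_alpha, xb_stage).astype(float)

    df.loc[is_case, "surgery"] = rng.random(m) < cc.surgery_prob

    log_hr = np.zeros(m)
    case_view = df.loc[is_case]
    for key, b in cc.survival_log_hrs.items():
        log_hr += b * _covariate(case_view, key, panel_ids)
    hazard = cc.survival_baseline_hazard * np.exp(log_hr)
    t_event = rng.exponential(1.0 / hazard)
    t_cens = rng.uniform(0.0, cc.censor_time, size=m)
    df.loc[is_case, "survival_time"] = np.round(np.maximum(np.minimum(t_event, t_cens), 0.1), 2)
    df.loc[is_case, "event"] = t_event <= t_cens

    evaluable = rng.random(m) < cc.evaluable_prob
    xb_resp = np.zeros(m)
    for key, b in cc.response_beta.items():
        xb_resp += b * _covariate(case_view, key, panel_ids)
    resp_codes = _ordinal_draw(rng, cc.response_alpha, xb_resp) - 1
    from .types import RESPONSE_LEVELS

    resp = pd.Series([RESPONSE_LEVELS[c] for c in resp_codes], index=case_view.index)
    df.loc[is_case, "response"] = resp.where(pd.Series(evaluable, index=case_view.index))

    truth = dict(sim.truth)
    truth["clinical"] = asdict(cc)
    return SimulatedCohort(CohortTable(df, panel_ids), truth, config)


@dataclass
class PowerEstimate:
    power: float
    ci: tuple[float, float]
    reps: int
    alpha: float
    test: str


def power_estimate(
    config: SimulationConfig,
    test: str = "pstar",
    alpha: float = 0.05,
    reps: int = 1000,
    seed: int | None = None,
    snp_id: str | None = None,
) -> PowerEstimate:
    """Monte-Carlo power (or size, when all ORs are 1) of an association test.

    For each replicate a cohort is generated under ``config`` and the chosen
    test is run: ``score_test_1df`` on the first stratum, ``pstar`` over
    both strata (both on ``snp_id``, default the first panel SNP), or
    ``gene_global_test`` combining the per-SNP P* values of the whole panel.
    Returns the rejection fraction at level ``alpha`` with a Wilson binomial
    CI. Replicate seeds derive from ``seed`` (default: config.seed).
    """
    from statsmodels.stats.proportion import proportion_confint

    from .association import gene_global_test, pstar, score_test_1df
    from .types import StratifiedGenotypeCounts

    if reps < 500:
        raise ValueError("reps must be >= 500")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if test in ("pstar", "gene_global_test") and len(config.sample_sizes) != 2:
        raise ValueError(f"{test} needs exactly two strata")
    snp_ids = [s.snp_id for s in config.panel]
    target = snp_id or snp_ids[0]
    j_target = snp_ids.index(target)
    strata = list(config.sample_sizes)

    def counts_for(dos_case, dos_ctrl, j, stratum) -> StratifiedGenotypeCounts:
        cc = tuple(int((dos_case[:, j] == d).sum()) for d in (2, 1, 0))
        kk = tuple(int((dos_ctrl[:, j] == d).sum()) for d in (2, 1, 0))
        return StratifiedGenotypeCounts(config.panel[j], stratum, cc, kk)

    rejected = 0
    for _ in range(reps):
        draws = {st: _draw_stratum(rng, config, st) for st in strata}
        if test == "score_test_1df":
            dc, dk = draws[strata[0]]
            _, p = score_test_1df(counts_for(dc, dk, j_target, strata[0]))
        elif test == "pstar":
            per = [counts_for(*draws[st], j_target, st) for st in strata]
            p = pstar(per[0], per[1]).pstar_p
        elif test == "gene_global_test":
            ps = []
            for j in range(len(snp_ids)):
                per = [counts_for(*draws[st], j, st) for st in strata]
                ps.append(pstar(per[0], per[1]).pstar_p)
            p = gene_global_test(ps).p_value
        else:
            raise ValueError(f"unknown test: {test}")
        if p < alpha:
            rejected += 1
    lo, hi = proportion_confint(rejected, reps, alpha=0.05, method="wilson")
    return PowerEstimate(power=rejected / reps, ci=(float(lo), float(hi)), reps=reps,
                         alpha=alpha, test=test)
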