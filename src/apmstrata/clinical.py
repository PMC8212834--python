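"""Clinical-endpoint models for the stratified SNP cohort.

Covers the robust Sn dispersion statistic, OR-weighted contrast ANOVA for
age at diagnosis, a Monte-Carlo Mahalanobis test for disease stage,
Kaplan-Meier / Cox proportional-hazards survival, and a proportional-odds
model for chemotherapy response with bootstrap confidence intervals.

Standard model fits are delegated to statsmodels (OLS, ordinal logistic)
and lifelines (Kaplan-Meier, Nelson-Aalen, Cox with Efron ties); the
study-specific statistics (Sn, OR-based contrasts, Mahalanobis Monte Carlo)
are implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import CohortTable, RESPONSE_LEVELS, Stratum


@dataclass
class SnStatistic:
    value: float
    n: int


@dataclass
class ContrastAnovaFit:
    cell_means: pd.DataFrame  # expected outcome per genotype x stratum cell
    f_stat: float
    p_value: float
    r_squared: float
    contrast: dict


@dataclass
class MahalanobisStageResult:
    d2: float
    p_mc: float
    n_mc: int
    seed: int | None
    group_means: dict


@dataclass
class SurvivalFit:
    km: "pd.DataFrame | None"
    cumulative_hazard: "pd.DataFrame | None"
    cox: "pd.DataFrame | None"
    flags: list = field(default_factory=list)


@dataclass
class OrdinalFit:
    alpha: np.ndarray  # thresholds, strictly increasing
    beta: dict[str, float]
    or_table: pd.DataFrame  # predictor, or, ci_low, ci_high
    log_likelihood: float
    flags: list = field(default_factory=list)


def sn_estimator(values: Sequence[float], consistency: bool = False) -> SnStatistic:
    """Robust scale statistic Sn = med_i { med_j |x_i - x_j| }.

    The inner median runs over all j = 1..n including j = i, and no
    consistency factor is applied by default (``consistency=True`` applies
    the 1.1926 normal-consistency constant). Location-invariant and
    scale-equivariant; 0 for a constant vector.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-d vector with n >= 2")
    diffs = np.abs(x[:, None] - x[None, :])
    inner = np.median(diffs, axis=1)
    value = float(np.median(inner))
    if consistency:
        value *= 1.1926
    return SnStatistic(value=value, n=len(x))


def or_contrast_weights(or_by_genotype: Mapping[int, float]) -> dict[int, float]:
    """Zero-sum contrast weights from per-genotype odds ratios.

    Weights are the centred natural logs of the genotype ORs (reference
    genotype OR = 1), so the contrast aligns with the direction and
    magnitude of disease risk.
    """
    logs = {g: math.log(v) for g, v in or_by_genotype.items()}
    mean = sum(logs.values()) / len(logs)
    w = {g: v - mean for g, v in logs.items()}
    if all(abs(v) < 1e-12 for v in w.values()):
        raise ValueError("all odds ratios equal; contrast is degenerate")
    return w


def aad_contrast_anova(
    cohort: CohortTable,
    snp: str,
    contrast_weights: Mapping,
    outcome: str = "age_at_diagnosis",
) -> ContrastAnovaFit:
    """F-test of an OR-derived genotype contrast on age at diagnosis.

    Fits a linear (cell-means) model of the outcome on genotype x smoking
    cells plus a sex adjustment, then tests the single contrast whose
    weights come from the genotype disease ORs. Weights may be keyed by
    genotype dosage (applied within every stratum) or by (dosage, stratum)
    pairs; they must sum to zero over the cells they touch.

    Returns the fit with expected (sex-adjusted) outcome per genotype x
    stratum cell and the model R^2.
    """
    import statsmodels.api as sm

    df = cohort.df[[outcome, snp, "stratum"] + (["sex"] if "sex" in cohort.df.columns else [])]
    df = df.dropna(subset=[outcome, snp]).copy()
    df[snp] = df[snp].astype(int)

    cells = sorted({(int(g), s) for g, s in zip(df[snp], df["stratum"])})
    # expand genotype-keyed weights across strata
    w_cells: dict[tuple[int, str], float] = {}
    for key, w in contrast_weights.items():
        if isinstance(key, tuple):
            w_cells[(int(key[0]), str(key[1]))] = float(w)
        else:
            for g, s in cells:
                if g == int(key):
                    w_cells[(g, s)] = float(w)
    touched = [c for c in cells if c in w_cells and abs(w_cells[c]) > 0]
    if abs(sum(w_cells.get(c, 0.0) for c in cells)) > 1e-8:
        raise ValueError("contrast weights must sum to zero over the design cells")
    missing_cells = [k for k in w_cells if k not in cells]
    if missing_cells:
        raise ValueError(f"contrast touches empty cells: {missing_cells}; inestimable")

    X = np.zeros((len(df), len(cells)))
    cell_of = {(g, s): j for j, (g, s) in enumerate(cells)}
    for i, (g, s) in enumerate(zip(df[snp], df["stratum"])):
        X[i, cell_of[(int(g), s)]] = 1.0
    names = [f"g{g}:{s}" for g, s in cells]
    Xdf = pd.DataFrame(X, columns=names, index=df.index)
    if "sex" in df.columns:
        Xdf["sex_adj"] = (df["sex"].astype(str) == "male").astype(float)
        Xdf["sex_adj"] -= Xdf["sex_adj"].mean()  # centred: cell params stay cell means
    model = sm.OLS(df[outcome].astype(float), Xdf).fit()

    cvec = np.zeros(Xdf.shape[1])
    for (g, s), w in w_cells.items():
        cvec[cell_of[(g, s)]] = w
    ft = model.f_test(cvec)
    ess = float(model.ess)
    r2 = ess / (ess + float(model.ssr)) if (ess + model.ssr) > 0 else 0.0

    cm = pd.DataFrame(
        [(g, s, model.params[f"g{g}:{s}"]) for g, s in cells],
        columns=["genotype", "stratum", "expected_outcome"],
    )
    return ContrastAnovaFit(
        cell_means=cm,
        f_stat=float(np.squeeze(ft.fvalue)),
        p_value=float(ft.pvalue),
        r_squared=float(r2),
        contrast={f"g{g}:{s}": w for (g, s), w in w_cells.items()},
    )


def stage_mahalanobis_mc(
    stage: Sequence[float],
    groups: Sequence,
    n_mc: int = 9999,
    seed: int | None = None,
    strata: Sequence | None = None,
) -> MahalanobisStageResult:
    """Monte-Carlo Mahalanobis test for group differences in disease stage.

    D^2 is the Mahalanobis distance of the vector of group mean stages from
    the grand mean under the pooled within-group variance, i.e.
    D^2 = sum_g n_g (m_g - m)^2 / s^2_pooled. The null distribution comes
    from permuting group labels n_mc times (globally, or within ``strata``
    when given); p = (1 + #{D^2* >= D^2}) / (n_mc + 1), so the p-value has
    resolution 1/(n_mc + 1).
    """
    if n_mc < 999:
        raise ValueError("n_mc must be >= 999")
    stage = np.asarray(stage, dtype=float)
    groups = np.asarray(groups)
    ok = ~np.isnan(stage)
    stage, groups = stage[ok], groups[ok]
    strata_arr = None if strata is None else np.asarray(strata)[ok]
    labels, idx = np.unique(groups, return_inverse=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")

    def d2(values: np.ndarray) -> float:
        means = np.array([values[idx == g].mean() for g in range(len(labels))])
        ns = np.array([(idx == g).sum() for g in range(len(labels))])
        within = sum(((values[idx == g] - means[g]) ** 2).sum() for g in range(len(labels)))
        dof = len(values) - len(labels)
        s2 = within / dof if dof > 0 else 0.0
        if s2 <= 0:
            warnings.warn("singular pooled variance; using total variance")
            s2 = values.var() or 1.0
        grand = values.mean()
        return float((ns * (means - grand) ** 2).sum() / s2)

    obs = d2(stage)
    rng = np.random.default_rng(seed)
    exceed = 0
    vals = stage.copy()
    stratum_masks = (
        None if strata_arr is None
        else [np.flatnonzero(strata_arr == s) for s in np.unique(strata_arr)]
    )
    for _ in range(n_mc):
        if stratum_masks is None:
            rng.shuffle(vals)
        else:
            for m in stratum_masks:
                vals[m] = vals[m][rng.permutation(len(m))]
        if d2(vals) >= obs:
            exceed += 1
    p = (1 + exceed) / (n_mc + 1)
    means = {str(l): float(stage[idx == g].mean()) for g, l in enumerate(labels)}
    return MahalanobisStageResult(d2=obs, p_mc=p, n_mc=n_mc, seed=seed, group_means=means)


def kaplan_meier(times: Sequence[float], events: Sequence[bool], alpha: float = 0.05):
    """Kaplan-Meier product-limit estimator with Greenwood 95% bands.

    Returns a lifelines ``KaplanMeierFitter``; ``fit.survival_function_``
    holds S(t) and ``fit.confidence_interval_`` the bands. Censored times
    shrink the risk set without creating steps.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    if (times <= 0).any():
        raise ValueError("times must be positive")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=np.asarray(events, dtype=bool))
    return kmf


def cox_ph(
    cohort: CohortTable | pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "survival_time",
    event_col: str = "event",
) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron tie handling via lifelines).

    Returns hazard ratios exp(beta) with Wald CIs per covariate, the
    Kaplan-Meier curve and Nelson-Aalen cumulative hazard of the fitted
    sample. Non-convergence or separation is reported in ``flags`` with the
    last iterate retained.
    """
    from lifelines import CoxPHFitter, KaplanMeierFitter, NelsonAalenFitter
    from lifelines.exceptions import ConvergenceError

    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    cols = [duration_col, event_col] + list(covariates)
    data = df[cols].dropna().copy()
    data[event_col] = data[event_col].astype(bool)
    if not data[event_col].any():
        raise ValueError("need at least one observed event")
    flags: list[str] = []
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            cph.fit(data, duration_col=duration_col, event_col=event_col)
        except ConvergenceError as exc:
            flags.append(f"non-convergence: {exc}")
            cph.fit(data, duration_col=duration_col, event_col=event_col,
                    fit_options={"max_steps": 5})
    summ = cph.summary[["coef", "exp(coef)", "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]]
    summ = summ.rename(columns={
        "exp(coef)": "hr", "exp(coef) lower 95%": "hr_low", "exp(coef) upper 95%": "hr_high",
    })
    if (summ["coef"].abs() > 10).any():
        flags.append("possible separation: |coef| > 10")
    kmf = KaplanMeierFitter().fit(data[duration_col], data[event_col])
    naf = NelsonAalenFitter().fit(data[duration_col], data[event_col])
    km = kmf.survival_function_.join(kmf.confidence_interval_)
    return SurvivalFit(km=km, cumulative_hazard=naf.cumulative_hazard_, cox=summ, flags=flags)


def survival_at(km_fit, months: Sequence[float]) -> pd.Series:
    """S(t) read off a fitted Kaplan-Meier curve at given time points."""
    return km_fit.predict(list(months))


def ordinal_response_model(
    cohort: CohortTable | pd.DataFrame,
    response: str,
    predictors: Sequence[str],
    reps: int = 2000,
    seed: int | None = None,
) -> OrdinalFit:
    """Proportional-odds (cumulative logit) model of an ordinal response.

    The response may be an ordered categorical (e.g. the chemotherapy
    response scale progressive < stable < partial < complete) or integer
    scores. Reported per-predictor ORs are exp(beta) with beta oriented so
    that OR > 1 means a shift toward *higher* (better) response categories.
    CIs are bootstrap percentile intervals over individual resamples
    (``reps=0`` skips the bootstrap and leaves the CIs as NaN).
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    if reps and reps < 1000:
        raise ValueError("reps must be >= 1000 for the bootstrap")
    df = cohort.df if isinstance(cohort, CohortTable) else cohort
    data = df[[response] + list(predictors)].dropna().copy()
    y = data[response]
    if y.dtype == object:
        levels = [l for l in RESPONSE_LEVELS if l in set(y)]
        y = pd.Categorical(y, categories=levels, ordered=True)
    else:
        levels = sorted(y.unique())
        y = pd.Categorical(y, categories=levels, ordered=True)
    if len(levels) < 2:
        raise ValueError("response needs >= 2 observed levels")
    X = data[list(predictors)].astype(float)

    def _fit(yv, Xv):
        if not isinstance(yv, pd.Series):
            yv = pd.Series(yv, index=Xv.index)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = OrderedModel(yv, Xv, distr="logit")
            return mod.fit(method="bfgs", disp=False)

    res = _fit(y, X)
    k = len(predictors)
    beta = dict(zip(predictors, res.params[:k]))
    thresh = res.model.transform_threshold_params(res.params)[1:-1]
    flags = []
    if any(abs(b) > 10 for b in beta.values()):
        flags.append("possible separation: |beta| > 10")

    rng = np.random.default_rng(seed)
    boot = np.full((max(reps, 1), k), np.nan)
    n = len(data)
    codes = np.asarray(pd.Categorical(y).codes)
    Xa = X.to_numpy()
    for r in range(reps):
        idx = rng.integers(0, n, size=n)
        yb = codes[idx]
        if len(np.unique(yb)) < 2:
            boot[r] = np.nan
            continue
        try:
            rb = _fit(pd.Categorical.from_codes(
                pd.factorize(yb, sort=True)[0],
                categories=[str(c) for c in sorted(np.unique(yb))], ordered=True),
                pd.DataFrame(Xa[idx], columns=list(predictors)))
            boot[r] = rb.params[:k]
        except Exception:
            boot[r] = np.nan
    if reps:
        lo = np.exp(np.nanquantile(boot, 0.025, axis=0))
        hi = np.exp(np.nanquantile(boot, 0.975, axis=0))
    else:
        lo = hi = np.full(k, np.nan)
    or_table = pd.DataFrame({
        "predictor": list(predictors),
        "or": [math.exp(beta[p]) for p in predictors],
        "ci_low": lo,
        "ci_high": hi,
    })
    return OrdinalFit(alpha=np.asarray(thresh), beta={p: float(b) for p, b in beta.items()},
                      or_table=or_table, log_likelihood=float(res.llf), flags=flags)
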