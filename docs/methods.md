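# Methods

This note records the statistical models the package implements, the
choices made where the published description left the construction open,
and what the synthetic-data tests do and do not establish.

## Data model and genotype coding

Each SNP is biallelic with a per-SNP minor allele defined from the control
group; individual genotypes are stored as minor-allele dosages 0/1/2 with
missing kept as missing. Individuals missing a genotype are excluded
per-SNP (pairwise deletion), which is why the bundled count tables have
different row totals across SNPs. All statistics consume either a
stratified 2×3 count table or the individual-level cohort table; no
statistical routine reads files.

## Odds ratios and intervals

Genotype odds ratios compare heterozygotes or minor homozygotes against the
major-homozygote reference. The Haldane–Anscombe correction (+0.5 in every
cell) is applied *unconditionally*, not only for zero cells: this is the
only convention that reproduces the published small-sample values (e.g.
2.56 vs the raw 2.81 for rs26653 CC/GG in smokers). The default interval is
Woolf's, exp(ln OR ± 1.96·√Σ1/(cell+½)); a percentile bootstrap (resampling
individuals within the case and control groups, ≥1000 replicates, seeded)
is available because the published intervals for sparse tables are
bootstrap-based and wider than Woolf's. The additive-model prediction for
the minor-homozygote OR is the square of the heterozygote OR.

## Hardy–Weinberg disequilibrium

f = (p_cc − p_c²)/(p_c(1−p_c)). The sign convention follows the formula:
f < 0 exactly when the minor-homozygote frequency falls below p_c²
(homozygote deficiency). The default test refers n·f² to χ²(1); the
Levene–Haldane exact test over heterozygote counts is available because
published p-values deviate from the χ² tail by ~5% relative and the exact
procedure used there is unknown.

## Per-stratum, per-SNP and gene-level tests

The per-stratum test is the Cochran–Armitage trend test with additive
scores (0,1,2), identical to the logistic-regression score test on dosage.
The per-SNP combined statistic P* is the sum of the two stratum statistics
referred to χ²(2); this construction reproduces the published P* for
rs2248374 (0.863 vs printed 0.861) but not for every SNP (rs26653: 0.036
vs printed 0.011) — the original derivation is not fully specified, and the
gene-level computation therefore accepts P* values as inputs. The
gene-level statistic is the Fisher combination −2Σ ln P*ₗ on 2L df. It
assumes independent per-SNP tests; for SNPs in linkage disequilibrium
(as in ERAP1) it is anti-conservative, which the type-I-error audit makes
visible: calibration is exact on a linkage-equilibrium panel (size ≈ 0.05)
and inflated (~0.10) on the LD-structured default panel. No multiplicity
correction is applied anywhere, matching the source analysis.

The Mantel–Haenszel common OR, its Robins–Breslow–Greenland interval and
the Breslow–Day homogeneity test with Tarone correction are delegated to
statsmodels; each stratum's 2×2 table excludes the third genotype. This
reproduces the published OR.MH = 0.85 (CI 0.62; 1.18) for rs26653
het-vs-ref exactly; the published homogeneity p-values do not reproduce
under Breslow–Day and the original "Breslow test" variant is unknown.

## Haplotype EM

Standard EM for phase-unknown genotypes: E-step weights each compatible
haplotype pair by 2^δ·p_h1·p_h2 under random within-group pairing, M-step
sets frequencies to expected haplotype counts over 2n chromosomes.
Individuals incomplete over the panel are excluded (not marginalised).
Convergence: max |Δfreq| < 10⁻⁸, at most 10⁴ iterations; the genotype
log-likelihood is non-decreasing across iterations and is checked against a
brute-force simplex-optimisation oracle on small instances. The default
start is the allele-frequency product ("counting"); a uniform start is
available, and symmetric ties (e.g. a lone double heterozygote) are left at
the symmetric fixed point rather than broken randomly, preferring
reproducibility over an arbitrary phase call. EM is run separately per
group (case/control within stratum).

Per-haplotype ORs use expected chromosome counts (2n·freq vs the rest) with
the +0.5 correction; the overall case-control haplotype test is a Pearson
χ² over the haplotype × group expected-count table on (#haplotypes − 1)
df, with sub-threshold haplotypes pooled into an explicit "other" category
(display threshold 1%). Published haplotype ORs are slightly larger than
what the printed frequencies imply (1.99 vs ≈1.78 recomputed); the original
estimator likely used individual-level posterior dosages, so neither
estimator is declared canonical. The bootstrap CI resamples individuals and
re-runs the EM when the cohort is supplied; given frequencies only, it
falls back to multinomial chromosome resampling — cheaper, and ignoring
phase uncertainty, hence slightly narrower intervals.

Pairwise LD is computed from 2-SNP EM frequencies: r² = D²/(p_A p_a p_B p_b),
D′ = |D|/D_max.

## Clinical models

- **Sn** is implemented exactly as the defining double median
  med_i med_j |x_i − x_j| with the inner median over all j including i and
  no consistency factor (the 1.1926 normal-consistency constant is an
  option). Units follow the input (years, months).
- **Age-at-diagnosis contrast ANOVA**: cell-means OLS on genotype × smoking
  cells with a centred sex adjustment; the tested contrast's weights are
  the centred log odds ratios of the genotypes (reference OR = 1), an
  interpretation of "contrasts based on the risks" — no formula was
  published, so the printed F statistics are not promised. R² is 1 −
  SSE/SST of the full model.
- **Stage**: D² = Σ n_g(m̄_g − m̄)²/s²_pooled over the group mean stages —
  the Mahalanobis distance of the group-mean vector from the grand mean
  under the pooled within-group variance. The null distribution is a
  global label permutation (a within-stratum option exists);
  p = (1 + #{D²* ≥ D²})/(n_mc + 1), resolution 1/(n_mc+1).
- **Survival**: Kaplan–Meier with Greenwood bands and Cox proportional
  hazards with Efron tie handling, via lifelines. Tied event times are
  expected (months); separation is flagged when |β| > 10.
- **Chemotherapy response**: proportional-odds cumulative logit
  (statsmodels OrderedModel), response ordered progressive < stable <
  partial < complete; β is oriented so OR = exp(β) > 1 means better
  response. CIs are percentile bootstrap over individuals (≥1000
  replicates, seeded; reps=0 skips the bootstrap).

## Synthetic cohorts

The generator states a world and sticks to it: controls pair two haplotypes
i.i.d. from the configured frequency map; disease follows a logistic model
whose per-genotype coefficients are the configured log ORs per stratum; the
cohort is sampled retrospectively to fixed case/control counts, matching
the case-control interpretation of the OR. The defaults mirror the study:
the six-SNP ERAP1/ERAP2 panel with the smokers' control haplotype
frequencies (thirteen haplotypes, 99.3% mass, renormalised), 387/173 smoker
and 57/156 never-smoker cases/controls. Clinical defaults are scale-matched
to the published cohort description: age at diagnosis N(64, 9²) years,
stage and response thresholds fitted to the printed marginal distributions,
exponential survival with median ≈ 12 months and uniform censoring at the
24-month follow-up horizon, 69% male, 47% surgery.

Hardy–Weinberg disequilibrium f ≥ 0 is injected by copying the first
haplotype with probability f (giving hom frequency p² + f·p(1−p) at every
SNP); f < 0 is rejected as infeasible under this construction. All
randomness flows from one mandatory seed; outputs embed a config hash.

What the generator does **not** emulate: genuine population LD decay or
recombination, covariate-dependent censoring, genotyping error and per-SNP
missingness mechanisms, or confounding between smoking and genotype. A
green recovery test therefore establishes internal consistency of
estimator and generator at realistic scale — not agreement with the
patient-level results, which are unavailable.

`power_estimate` replays the generator and reports the rejection fraction
of a chosen test (trend, P*, gene-level) with a Wilson binomial CI; at all
ORs = 1 it measures size.

## Numerical conventions

Display rounding follows the source tables (ORs and f to 2 decimals,
statistics to 1, p-values to 3 significant figures); all computation is at
double precision. Zero dosage variance yields statistic 0, p = 1;
monomorphic SNPs give flagged, NaN-valued HWE and LD results; a zero cell
without the continuity correction is an error instructing to enable it.
P* = 0 inputs to the gene-level combination are rejected (infinite
statistic). Scan failures for one SNP are flagged rows, never aborts.

## Known limitations

The exact published constructions for P*, the Breslow homogeneity p, the
HWE p-values and the haplotype OR estimator are not recoverable from the
description; this package documents its choices and reproduces the values
those choices imply. The gene-level combination inherits the independence
assumption noted above. The EM excludes panel-incomplete individuals rather
than marginalising over missing sites.
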