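import itertools

import numpy as np
import pandas as pd
import pytest

from apmstrata import CohortTable, SnpDef, Stratum, default_config, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_cohort():
    """50-individual synthetic cohort over the default six-SNP panel."""
    cfg = default_config(seed=123)
    cfg.sample_sizes = {Stratum.SMOKERS: (15, 10), Stratum.NEVER_SMOKERS: (10, 15)}
    return simulate_genotypes(cfg).cohort


def make_cohort(dosages: np.ndarray, status=None, stratum=None, snp_ids=None) -> CohortTable:
    """Assemble a CohortTable from a raw dosage matrix."""
    n, L = dosages.shape
    snp_ids = snp_ids or [f"rs{i + 1}" for i in range(L)]
    df = pd.DataFrame(dosages.astype(float), columns=snp_ids)
    df.insert(0, "stratum", stratum if stratum is not None else "smokers")
    df.insert(0, "status", status if status is not None else "case")
    df.insert(0, "id", [f"i{i}" for i in range(n)])
    return CohortTable(df, snp_ids)


def brute_force_haplotype_ml(dosages: np.ndarray, n_restarts: int = 12, seed: int = 0):
    """Independent maximum-likelihood oracle for haplotype frequencies.

    Enumerates every ordered haplotype pair over all 2^L haplotypes whose
    dosage sum matches each genotype, and maximises the multinomial
    likelihood over the frequency simplex numerically (softmax
    parametrisation, multiple restarts). Only feasible for tiny panels.
    """
    from scipy.optimize import minimize

    dosages = dosages[~np.isnan(dosages).any(axis=1)].astype(int)
    L = dosages.shape[1]
    haps = list(itertools.product((0, 1), repeat=L))
    H = len(haps)
    pair_idx = []
    for g in dosages:
        idx = [
            (i, j)
            for i, h1 in enumerate(haps)
            for j, h2 in enumerate(haps)
            if all(a + b == d for a, b, d in zip(h1, h2, g))
        ]
        pair_idx.append(np.array(idx))

    def negll(theta):
        p = np.exp(theta - theta.max())
        p = p / p.sum()
        ll = 0.0
        for idx in pair_idx:
            tot = (p[idx[:, 0]] * p[idx[:, 1]]).sum()
            if tot <= 0:
                return 1e12
            ll += np.log(tot)
        return -ll

    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_restarts):
        res = minimize(negll, rng.normal(size=H), method="Nelder-Mead",
                       options={"maxiter": 20000, "xatol": 1e-10, "fatol": 1e-12})
        best = min(best, res.fun)
    return -best
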