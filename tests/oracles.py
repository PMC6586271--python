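"""Independent reference implementations used only to check the package.

These deliberately take different computational routes from the library:
the fixation-index oracle runs the nested analysis-of-variance on allele
copies (sums of squares and mean squares) instead of the closed-form
frequency expressions, and the Hardy-Weinberg oracle enumerates every
allele pairing exhaustively.
"""

from __future__ import annotations

import itertools

import numpy as np

MISSING = -1


def anova_theta_components(calls: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Weir-Cockerham variance components by explicit nested ANOVA.

    Allele copies nest in individuals nest in populations.  For each locus:
    SSG (within individuals), SSI (among individuals within populations) and
    SSP (among populations) with degrees of freedom N, N - r, r - 1 give the
    mean squares, from which sigma^2_within = MSG, sigma^2_ind =
    (MSI - MSG)/2 and sigma^2_pop = (MSP - MSI)/(2 nc).
    """
    calls = np.asarray(calls)
    codes = np.asarray(codes)
    n_loci = calls.shape[1]
    out = np.full((n_loci, 3), np.nan)
    for j in range(n_loci):
        y, pop = [], []
        for i in range(calls.shape[0]):
            if calls[i, j] != MISSING and codes[i] >= 0:
                y.append(float(calls[i, j]))
                pop.append(codes[i])
        y = np.array(y)
        pop = np.array(pop)
        pops = np.unique(pop)
        r = pops.size
        if r < 2:
            continue
        n_i = np.array([(pop == p).sum() for p in pops], dtype=float)
        N = n_i.sum()
        if N == r:  # every population a single individual: no within-pop df
            continue
        p_i = np.array([y[pop == p].mean() / 2.0 for p in pops])
        p_bar = (n_i * p_i).sum() / N
        ssg = float((y == 1).sum()) * 0.5
        ssi = sum(2.0 * ((y[pop == p] / 2.0 - p_i[k]) ** 2).sum()
                  for k, p in enumerate(pops))
        ssp = float((2.0 * n_i * (p_i - p_bar) ** 2).sum())
        msg = ssg / N
        msi = ssi / (N - r)
        msp = ssp / (r - 1)
        nc = (N - (n_i ** 2).sum() / N) / (r - 1)
        c = msg
        b = (msi - msg) / 2.0
        a = (msp - msi) / (2.0 * nc)
        out[j] = (a, b, c)
    return out


def anova_theta(calls, codes, multi_locus=False):
    comp = anova_theta_components(calls, codes)
    if multi_locus:
        s = np.nansum(comp, axis=0)
        return s[0] / s.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        return comp[:, 0] / comp.sum(axis=1)


def hwe_exact_pairing_p(calls: np.ndarray) -> float:
    """Exact permutation p-value of the Hardy-Weinberg chi-square by full
    enumeration of every ordering of the sample's allele copies paired into
    consecutive diploids.  Feasible for a handful of individuals."""
    calls = np.asarray(calls)
    n = calls.size
    n_het = int((calls == 1).sum())
    n_alt_alleles = int(calls.sum())
    alleles = [1] * n_alt_alleles + [0] * (2 * n - n_alt_alleles)

    def chi2_of(genos):
        counts = np.bincount(genos, minlength=3)
        p = n_alt_alleles / (2.0 * n)
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        return float(((counts - exp) ** 2 / exp).sum())

    chi2_obs = chi2_of(np.asarray(calls))
    hits = total = 0
    for perm in itertools.permutations(alleles):
        genos = np.array([perm[2 * i] + perm[2 * i + 1] for i in range(n)])
        total += 1
        if chi2_of(genos) >= chi2_obs - 1e-12:
            hits += 1
    return hits / total
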